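"""Desk-scale benchmark experiments.

These are the simulation studies the package runs on itself: type-I
calibration on null panels, detection power on causal panels, profile
recovery, crossover-law checks, and planted-motif recovery.  Tests and
the acceptance script both call these functions so the reported numbers
always come from the same code paths.

Study conditions (chosen once; see docs/methods.md for rationale):

* simulator: desk preset (N = 500 diploids, 300 generations, 40 SNPs on
  200 kb, subsets of 90 individuals = 180 haplotypes), site-independent
  standing variation, hot/cold crossover probabilities 0.01/0.001 with
  crossover positions Normal(100 kb, 1 kb);
* null panels: the hotspot fires for every meiosis (no allele controls
  it) — the null of no allele-dependence, not of no recombination;
* analysis: scans run on a window of +/-5 sites (~25 kb) around the
  hotspot center, keeping sites with MAF >= 0.10; candidate SNPs need
  MAF >= 0.30; hotspot strength integrates rho over [99, 101] kb;
* estimator: the desk preset of :class:`~ldsplit.recprofile.EstimatorConfig`.
"""

from __future__ import annotations

import numpy as np

from . import fwdsim, motifpipe
from .core import permutation_pvalue, scan_hotspot
from .hapio import HaplotypePanel, maf
from .recprofile import EstimatorConfig, estimate_profile, hotspot_strength

__all__ = [
    "HOTSPOT_INTERVAL_BP",
    "informative_sites",
    "analysis_window",
    "simulate_null_panels",
    "simulate_causal_datasets",
    "type1_experiment",
    "power_experiment",
    "profile_recovery_experiment",
    "crossover_law_experiment",
    "motif_recovery_experiment",
]

HOTSPOT_INTERVAL_BP = (99_000.0, 101_000.0)
SITE_MAF_MIN = 0.10
CANDIDATE_MAF_MIN = 0.30
WINDOW_HALF_SITES = 5


def informative_sites(panel: HaplotypePanel, maf_min: float = SITE_MAF_MIN) -> HaplotypePanel:
    """Drop fixed and rare sites; the analysis mirrors real SNP panels,
    which only contain common polymorphisms."""
    keep = [
        j
        for j in range(panel.n_sites)
        if (panel.alleles[:, j] == 0).any()
        and (panel.alleles[:, j] == 1).any()
        and maf(panel, j) >= maf_min
    ]
    return panel.take_sites(keep)


def analysis_window(
    panel: HaplotypePanel,
    center_bp: float = 100_000.0,
    half_width: int = WINDOW_HALF_SITES,
    maf_min: float = SITE_MAF_MIN,
) -> HaplotypePanel:
    """The scan window: +/-``half_width`` sites around the hotspot
    center, restricted to informative sites."""
    w = panel.cut_window(panel.site_index_at_bp(center_bp), half_width)
    return informative_sites(w, maf_min)


def simulate_null_panels(
    n_panels: int, seed: int = 0, subsets_per_pop: int = 10
) -> list[HaplotypePanel]:
    """Panels from populations whose hotspot is not under allele control."""
    panels: list[HaplotypePanel] = []
    s = 0
    while len(panels) < n_panels:
        cfg = fwdsim.SimulationConfig.desk_null(
            seed=motifpipe.derive_seed(seed, 11, s), n_subsets=subsets_per_pop
        )
        pop = fwdsim.initialize_population(cfg)
        fwdsim.evolve(pop, cfg, rng=np.random.default_rng(cfg.seed + 1))
        panels.extend(fwdsim.sample_panels(pop, cfg))
        s += 1
    return panels[:n_panels]


def simulate_causal_datasets(
    n_populations: int = 5,
    subsets_per_pop: int = 2,
    seed: int = 0,
) -> list[dict]:
    """Conditioned causal-hotspot populations, sampled into datasets.

    Each record carries the benchmark panel, the causal position and the
    source population.
    """
    out = []
    for s in range(n_populations):
        cfg = fwdsim.SimulationConfig.desk(
            seed=motifpipe.derive_seed(seed, 22, s), n_subsets=subsets_per_pop
        )
        pop = fwdsim.run_conditioned(cfg, max_attempts=30)
        for panel in fwdsim.sample_panels(pop, cfg):
            out.append(
                {
                    "panel": panel,
                    "config": cfg,
                    "causal_pos_bp": float(pop.positions_bp[pop.causal_index]),
                    "final_hot_freq": pop.freq_trace[-1],
                }
            )
    return out


def _central_candidate(panel: HaplotypePanel, center_bp: float = 100_000.0) -> int:
    """The candidate SNP nearest the hotspot center with MAF >= 0.30
    (falling back to the nearest polymorphic site)."""
    order = np.argsort(np.abs(panel.positions_bp - center_bp))
    for j in order:
        col = panel.alleles[:, j]
        if (col == 0).any() and (col == 1).any() and maf(panel, int(j)) >= CANDIDATE_MAF_MIN:
            return int(j)
    return int(order[0])


def type1_experiment(n_panels: int = 200, n_perm: int = 99, seed: int = 0) -> dict:
    """Reject rate at p < 0.05 for the central candidate SNP on null panels."""
    panels = simulate_null_panels(n_panels, seed=seed)
    estimator = EstimatorConfig.desk(seed=0)
    p_values = []
    for k, panel in enumerate(panels):
        w = analysis_window(panel)
        cand = _central_candidate(w)
        res = permutation_pvalue(
            w,
            cand,
            HOTSPOT_INTERVAL_BP,
            estimator=estimator,
            n_perm=n_perm,
            seed=motifpipe.derive_seed(seed, 33, k),
        )
        p_values.append(res.p_value)
    p = np.asarray(p_values)
    return {
        "n_panels": n_panels,
        "n_perm": n_perm,
        "p_values": p,
        "n_rejected": int((p < 0.05).sum()),
        "rejection_rate": float((p < 0.05).mean()),
    }


def power_experiment(
    n_populations: int = 5,
    subsets_per_pop: int = 2,
    n_perm: int = 99,
    seed: int = 0,
) -> dict:
    """Scan causal datasets: causal-SNP rank, hot-vs-cold strength, and
    significant-SNP counts per dataset."""
    datasets = simulate_causal_datasets(n_populations, subsets_per_pop, seed=seed)
    estimator = EstimatorConfig.desk(seed=0)
    records = []
    for k, ds in enumerate(datasets):
        w = analysis_window(ds["panel"])
        cw = int(np.argmin(np.abs(w.positions_bp - ds["causal_pos_bp"])))
        causal_in_window = abs(w.positions_bp[cw] - ds["causal_pos_bp"]) < 1.0
        table = scan_hotspot(
            w,
            HOTSPOT_INTERVAL_BP,
            maf_min=CANDIDATE_MAF_MIN,
            estimator=estimator,
            n_perm=n_perm,
            seed=motifpipe.derive_seed(seed, 44, k),
        )
        ps = np.array([r.p_value for r in table.results])
        causal_res = next((r for r in table.results if r.snp_index == cw), None)
        rec = {
            "n_candidates": len(table.results),
            "n_significant": int((ps < 0.05).sum()),
            "causal_in_table": causal_res is not None and causal_in_window,
            "causal_p": causal_res.p_value if causal_res else np.nan,
            "causal_is_top": bool(
                causal_res is not None and ps.size and causal_res.p_value <= ps.min()
            ),
            "hot_stronger": bool(causal_res and causal_res.rho1 > causal_res.rho0),
            "table": table,
            "causal_site_in_window": cw,
        }
        records.append(rec)
    return {
        "datasets": records,
        "causal_top_fraction": float(np.mean([r["causal_is_top"] for r in records])),
        "hot_stronger_fraction": float(np.mean([r["hot_stronger"] for r in records])),
        "mean_significant": float(np.mean([r["n_significant"] for r in records])),
    }


def profile_recovery_experiment(n_reps: int = 10, seed: int = 0) -> dict:
    """Does the profile argmax land on the hotspot?  And are profiles from
    flat (uniform crossover position) simulations flat?"""
    estimator = EstimatorConfig.desk(seed=0)
    hits = 0
    for r in range(n_reps):
        cfg = fwdsim.SimulationConfig.desk(
            seed=motifpipe.derive_seed(seed, 55, r), n_subsets=1
        )
        pop = fwdsim.run_conditioned(cfg, max_attempts=30)
        panel = informative_sites(fwdsim.sample_panels(pop, cfg)[0])
        prof = estimate_profile(panel, estimator)
        am = int(np.argmax(prof.interval_rho))
        lo, hi = prof.positions_kb[am] * 1000, prof.positions_kb[am + 1] * 1000
        if lo < HOTSPOT_INTERVAL_BP[1] and hi > HOTSPOT_INTERVAL_BP[0]:
            hits += 1
    ratios = []
    for r in range(n_reps):
        cfg = fwdsim.SimulationConfig.desk_null(
            seed=motifpipe.derive_seed(seed, 66, r),
            n_subsets=1,
            xover_position_dist="uniform",
        )
        pop = fwdsim.initialize_population(cfg)
        fwdsim.evolve(pop, cfg, rng=np.random.default_rng(cfg.seed + 1))
        panel = informative_sites(fwdsim.sample_panels(pop, cfg)[0])
        prof = estimate_profile(panel, estimator)
        med = float(np.median(prof.interval_rho))
        ratios.append(float(prof.interval_rho.max() / med) if med > 0 else np.inf)
    return {
        "hotspot_argmax_hits": hits,
        "n_reps": n_reps,
        "argmax_hit_fraction": hits / n_reps,
        "flat_max_median_ratios": np.asarray(ratios),
        "flat_mean_ratio": float(np.mean(ratios)),
    }


def crossover_law_experiment(n_meioses: int = 100_000, seed: int = 0) -> dict:
    """Empirical crossover rate and position distribution from repeated
    meioses of hot- and cold-genotype parents."""
    cfg = fwdsim.SimulationConfig.desk(seed=seed)
    pos = fwdsim.site_positions(cfg)
    ci = fwdsim.causal_index(cfg)
    L = pos.size
    rng = np.random.default_rng(seed)
    hot_parent = rng.integers(0, 2, size=(2, L)).astype(np.int8)
    hot_parent[:, ci] = 1
    cold_parent = rng.integers(0, 2, size=(2, L)).astype(np.int8)
    cold_parent[:, ci] = 0
    results = {}
    positions = []
    for name, parent, p_expected in (
        ("hot", hot_parent, cfg.p_xover_hot),
        ("cold", cold_parent, cfg.p_xover_background),
    ):
        crossed = 0
        for _ in range(n_meioses):
            _, det = fwdsim.meiosis(parent, cfg, rng, positions_bp=pos, detail=True)
            if det.crossed:
                crossed += 1
                positions.append(det.position_bp)
        results[name] = {
            "n": n_meioses,
            "crossed": crossed,
            "rate": crossed / n_meioses,
            "expected": p_expected,
        }
    results["positions_bp"] = np.asarray(positions)
    return results


def motif_recovery_experiment(
    seed: int = 0,
    n_windows: int = 60,
    n_planted_each: int = 25,
    motifs: tuple[str, str] = ("ACTATCGATCTAG", "ATGATGTAATGGT"),
    width_min: int = 10,
    width_max: int = 20,
    min_sites: int = 10,
    n_restarts: int = 4,
    n_starts: int = 150,
) -> dict:
    """Plant the two benchmark 13-mers across significant-SNP windows and
    check ranked recovery; repeat without planting as the control.

    Windows are 101-base random sequences standing in for the flanks of
    SNPs flagged by the scan; the two motifs are planted spanning the
    central (causal-SNP) position in disjoint window subsets, the rest
    are left unplanted (the scan's false positives).
    """
    rng = np.random.default_rng(motifpipe.derive_seed(seed, 77))
    bases = "ACGT"

    def random_record(i, tag):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        s = "".join(rng.choice(list(bases), size=101))
        rec = SeqRecord(Seq(s), id=f"{tag}_{i}", description="synthetic flank window")
        rec.annotations = {"snp_offset": 50}
        return rec

    records = [random_record(i, "win") for i in range(n_windows)]
    ids = [r.id for r in records]
    set_a = set(ids[:n_planted_each])
    set_b = set(ids[n_planted_each : 2 * n_planted_each])
    planted = motifpipe.plant_motifs(
        records, motifs[0], set_a, seed=motifpipe.derive_seed(seed, 78)
    )
    planted = motifpipe.plant_motifs(
        planted, motifs[1], set_b, seed=motifpipe.derive_seed(seed, 79)
    )
    found = motifpipe.discover_motifs(
        planted,
        n_motifs=2,
        width_min=width_min,
        width_max=width_max,
        min_sites=min_sites,
        n_restarts=n_restarts,
        n_starts=n_starts,
        seed=motifpipe.derive_seed(seed, 80),
    )
    matches = {
        m: [motifpipe.consensus_match(pwm, m) for pwm in found] for m in motifs
    }
    control_records = [random_record(i, "ctl") for i in range(n_windows)]
    control_found = motifpipe.discover_motifs(
        control_records,
        n_motifs=2,
        width_min=width_min,
        width_max=width_max,
        min_sites=min_sites,
        n_restarts=n_restarts,
        n_starts=n_starts,
        seed=motifpipe.derive_seed(seed, 81),
    )
    control_matches = {
        m: [motifpipe.consensus_match(pwm, m) for pwm in control_found] for m in motifs
    }
    return {
        "found": found,
        "matches": matches,
        "best_match": {m: max(v) if v else 0.0 for m, v in matches.items()},
        "control_found": control_found,
        "control_matches": control_matches,
        "control_best": {
            m: max(v) if v else 0.0 for m, v in control_matches.items()
        },
    }
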