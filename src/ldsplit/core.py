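"""The allele-split association statistic.

For a candidate SNP the panel is divided into the two allele-defined
subpopulations, a recombination profile is estimated for each, and the
normalized difference of hotspot strengths

    delta_rho = (rho0 - rho1) / (rho0 + rho1)

is compared against a null distribution obtained by randomly re-splitting
the rows into pseudo-populations of the same sizes.  The permutation
p-value uses the add-one estimator (k + 1) / (N + 1) and is two-sided on
|delta_rho| by default (screening has no a-priori direction); a one-sided
variant is exposed for the motif-disruption use case.

Null splits are canonicalised to subsets of size min(n0, n1), which makes
the two-sided p-value exactly invariant under relabeling the SNP's
alleles.  When the number of distinct splits is small the null is
enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .hapio import MISSING, HaplotypePanel, maf
from .recprofile import (
    EstimatorConfig,
    EstimationError,
    NoInformationError,
    RecombinationProfile,
    estimate_profile,
    hotspot_strength,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitError",
    "AlleleMismatchError",
    "SplitResult",
    "ScanTable",
    "split_by_allele",
    "delta_rho",
    "permutation_pvalue",
    "scan_hotspot",
    "classify_motif_allele",
]


class SplitError(ValueError):
    """Raised when a site cannot be used to split the panel."""


class AlleleMismatchError(ValueError):
    """Raised when motif-occurrence alleles do not match the panel coding."""


def split_by_allele(panel: HaplotypePanel, site_index: int) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Partition rows by the allele carried at ``site_index``.

    Rows with a missing call at the site are excluded (logged).  Each
    subpanel is monomorphic at the split site; input row order is
    preserved within each subpanel.
    """
    col = panel.alleles[:, site_index]
    rows0 = np.flatnonzero(col == 0)
    rows1 = np.flatnonzero(col == 1)
    n_miss = int(np.sum(col == MISSING))
    if n_miss:
        logger.info("split_by_allele: excluded %d rows missing at site %d", n_miss, site_index)
    if rows0.size == 0 or rows1.size == 0:
        raise SplitError(f"site {site_index} is monomorphic; cannot split")
    return panel.take_rows(rows0), panel.take_rows(rows1)


def delta_rho(rho0: float, rho1: float) -> float:
    """Normalized strength difference (rho0 - rho1) / (rho0 + rho1).

    Defined as 0 when both strengths are 0 (no evidence of difference).
    """
    if rho0 < 0 or rho1 < 0:
        raise ValueError("hotspot strengths must be non-negative")
    tot = rho0 + rho1
    if tot == 0:
        return 0.0
    return (rho0 - rho1) / tot


@dataclass
class SplitResult:
    """Outcome of the permutation test at one candidate SNP."""

    snp_index: int
    position: float  # in the panel's unit
    allele0_count: int
    allele1_count: int
    rho0: float
    rho1: float
    delta_rho: float
    p_value: float
    n_permutations: int
    null_deltas: np.ndarray = field(repr=False)
    seed: int | None = None
    exhaustive: bool = False


def _strength_for_rows(
    panel: HaplotypePanel,
    rows: np.ndarray,
    interval_bp,
    config: EstimatorConfig,
    context: str,
    degenerate_strength: str = "zero",
) -> float:
    sub = panel.take_rows(rows)
    try:
        profile = estimate_profile(sub, config)
    except NoInformationError:
        # a diversity-free subpanel shows no evidence of historical
        # recombination; by convention its strength is 0
        if degenerate_strength == "zero":
            logger.info(
                "split %r has <2 segregating sites; hotspot strength set to 0", context
            )
            return 0.0
        raise EstimationError(
            f"estimation failed for split {context!r}: no segregating variation"
        )
    except EstimationError as exc:
        raise EstimationError(f"estimation failed for split {context!r}: {exc}") from exc
    return hotspot_strength(profile, interval_bp)


def _n_distinct_splits(n: int, m: int) -> int:
    """Distinct unordered splits into sizes (m, n - m) with m = min size."""
    total = comb(n, m)
    return total // 2 if 2 * m == n else total


def permutation_pvalue(
    panel: HaplotypePanel,
    site_index: int,
    hotspot_interval,
    estimator: EstimatorConfig | None = None,
    n_perm: int = 200,
    seed: int = 0,
    one_sided: bool = False,
    degenerate_strength: str = "zero",
) -> SplitResult:
    """Observed delta_rho at a SNP and its size-matched permutation null.

    The observed statistic comes from the allele split; null values come
    from uniformly random splits of the same rows into groups of sizes
    (n0, n1).  ``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)``.  When
    ``n_perm`` reaches the number of distinct splits the null is
    enumerated exhaustively (and ``n_permutations`` reflects that count).
    Reproducible given ``seed``; every split uses the identical
    estimator configuration.
    """
    config = estimator or EstimatorConfig()
    col = panel.alleles[:, site_index]
    keep_rows = np.flatnonzero(col != MISSING)
    work = panel.take_rows(keep_rows) if keep_rows.size != panel.n_haplotypes else panel
    col = work.alleles[:, site_index]
    rows0 = np.flatnonzero(col == 0)
    rows1 = np.flatnonzero(col == 1)
    if rows0.size == 0 or rows1.size == 0:
        raise SplitError(f"site {site_index} is monomorphic; cannot test")

    rho0 = _strength_for_rows(work, rows0, hotspot_interval, config, "allele0", degenerate_strength)
    rho1 = _strength_for_rows(work, rows1, hotspot_interval, config, "allele1", degenerate_strength)
    obs = delta_rho(rho0, rho1)

    n = work.n_haplotypes
    m = min(rows0.size, rows1.size)
    n_distinct = _n_distinct_splits(n, m)
    rng = np.random.default_rng(seed)
    all_rows = np.arange(n)

    null = []
    if n_perm >= n_distinct:
        # exhaustive: canonical subsets of the minority size; with equal
        # sizes keep only subsets containing row 0 (complement duals).
        for idx, combo in enumerate(itertools.combinations(range(n), m)):
            if 2 * m == n and 0 not in combo:
                continue
            a = np.array(combo, dtype=int)
            b = np.setdiff1d(all_rows, a)
            ra = _strength_for_rows(work, a, hotspot_interval, config, f"perm{idx}A", degenerate_strength)
            rb = _strength_for_rows(work, b, hotspot_interval, config, f"perm{idx}B", degenerate_strength)
            null.append(delta_rho(ra, rb))
        exhaustive = True
    else:
        for i in range(n_perm):
            a = rng.choice(n, size=m, replace=False)
            b = np.setdiff1d(all_rows, a)
            ra = _strength_for_rows(work, a, hotspot_interval, config, f"perm{i}A", degenerate_strength)
            rb = _strength_for_rows(work, b, hotspot_interval, config, f"perm{i}B", degenerate_strength)
            null.append(delta_rho(ra, rb))
        exhaustive = False
    null = np.asarray(null)
    if one_sided:
        k = int(np.sum(null >= obs))
    else:
        k = int(np.sum(np.abs(null) >= abs(obs)))
    p = (1 + k) / (null.size + 1)
    return SplitResult(
        snp_index=site_index,
        position=float(panel.positions[site_index]),
        allele0_count=int(rows0.size),
        allele1_count=int(rows1.size),
        rho0=rho0,
        rho1=rho1,
        delta_rho=obs,
        p_value=p,
        n_permutations=int(null.size),
        null_deltas=null,
        seed=seed,
        exhaustive=exhaustive,
    )


@dataclass
class ScanTable:
    """One :class:`SplitResult` per qualifying SNP, plus provenance."""

    results: list[SplitResult]
    hotspot_interval: tuple[float, float]
    maf_min: float
    panel_hash: str
    config: EstimatorConfig
    profile: RecombinationProfile | None = None
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "position": r.position,
                "rs_label": f"site_{r.snp_index}",
                "n0": r.allele0_count,
                "n1": r.allele1_count,
                "rho0": r.rho0,
                "rho1": r.rho1,
                "delta_rho": r.delta_rho,
                "p_value": r.p_value,
                "n_perm": r.n_permutations,
                "seed": r.seed,
            }
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "position",
                "rs_label",
                "n0",
                "n1",
                "rho0",
                "rho1",
                "delta_rho",
                "p_value",
                "n_perm",
                "seed",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _panel_hash(panel: HaplotypePanel) -> str:
    h = hashlib.sha1()
    h.update(panel.alleles.tobytes())
    h.update(np.ascontiguousarray(panel.positions).tobytes())
    return h.hexdigest()[:16]


def scan_hotspot(
    panel: HaplotypePanel,
    hotspot_interval,
    maf_min: float = 0.30,
    estimator: EstimatorConfig | None = None,
    n_perm: int = 200,
    seed: int = 0,
    one_sided: bool = False,
) -> ScanTable:
    """Permutation-test every SNP with MAF >= ``maf_min`` against a hotspot.

    Per-SNP permutation streams are derived deterministically from
    ``seed`` and the site index, so the observed delta_rho column does
    not depend on the permutation seed.  The whole-panel profile is
    estimated once and stored on the table.
    """
    config = estimator or EstimatorConfig()
    candidates = []
    for j in range(panel.n_sites):
        col = panel.alleles[:, j]
        if not (np.any(col == 0) and np.any(col == 1)):
            continue
        if maf(panel, j) >= maf_min:
            candidates.append(j)
    if not candidates:
        logger.warning("scan_hotspot: no SNP passes MAF >= %.2f", maf_min)
    try:
        profile = estimate_profile(panel, config)
    except EstimationError:
        profile = None
    results = []
    for j in candidates:
        child_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))
        results.append(
            permutation_pvalue(
                panel,
                j,
                hotspot_interval,
                estimator=config,
                n_perm=n_perm,
                seed=child_seed,
                one_sided=one_sided,
            )
        )
    return ScanTable(
        results=results,
        hotspot_interval=(float(hotspot_interval[0]), float(hotspot_interval[1])),
        maf_min=maf_min,
        panel_hash=_panel_hash(panel),
        config=config,
        profile=profile,
        seed=seed,
    )


def classify_motif_allele(result: SplitResult, occurrence, allele_bases: dict) -> str:
    """Classify a motif-SNP as ``"positive"`` or ``"negative"``.

    ``allele_bases`` maps the panel's 0/1 coding at the SNP to DNA bases
    (on the occurrence's reference strand).  Positive means the
    motif-preserving allele has the strictly higher estimated hotspot
    strength; ties classify as negative with a logged flag.
    """
    inv = {v.upper(): k for k, v in allele_bases.items()}
    pres = occurrence.preserving_allele.upper()
    disr = occurrence.disrupting_allele.upper()
    if pres not in inv or disr not in inv or inv[pres] == inv[disr]:
        raise AlleleMismatchError(
            f"occurrence alleles {pres}/{disr} do not match panel coding {allele_bases}"
        )
    strength = {0: result.rho0, 1: result.rho1}
    s_pres = strength[inv[pres]]
    s_disr = strength[inv[disr]]
    if s_pres == s_disr:
        logger.info(
            "classify_motif_allele: tied strengths at site %d; classifying negative",
            result.snp_index,
        )
        return "negative"
    return "positive" if s_pres > s_disr else "negative"
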