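"""Motif-centric stage: SNP-containing motif occurrences, flank windows,
motif planting, and a built-in OOPS expectation-maximization motif finder.

``find_motif_occurrences_with_snp`` locates windows of a reference where
one allele of a SNP completes an exact motif match on either strand —
identifying, per occurrence, the *preserving* and the *disrupting*
allele.  ``snp_flank_sequences`` cuts fixed-width windows (101 bases by
default) around SNPs; ``plant_motifs`` overwrites benchmark motifs into
such windows spanning the central SNP.  ``oops_em`` / ``discover_motifs``
re-implement the classic one-occurrence-per-sequence EM over a position
weight matrix, with both strands in the latent variable, multi-restart,
and BIC-style ranking with site masking between ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SnpVariant",
    "MotifOccurrence",
    "PWM",
    "find_motif_occurrences_with_snp",
    "snp_flank_sequences",
    "plant_motifs",
    "OopsEm",
    "oops_em",
    "discover_motifs",
    "consensus_match",
    "derive_seed",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed from a master seed and integer keys."""
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SnpVariant:
    """A biallelic SNP on a reference sequence (0-based position)."""

    sequence_id: str
    position: int
    alleles: tuple[str, str]


@dataclass
class MotifOccurrence:
    """An exact motif match completed by one allele of a contained SNP."""

    sequence_id: str
    start: int  # 0-based on the reference (+) strand
    strand: str  # '+' or '-'
    motif_text: str
    snp_offset: int  # offset within motif_text, on the occurrence's strand
    preserving_allele: str  # reference-strand base completing the motif
    disrupting_allele: str
    disrupted_text: str
    ref_mismatch: bool = False  # neither allele equals the reference base

    @property
    def end(self) -> int:
        return self.start + len(self.motif_text)


def _normalize_reference(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return {k: str(v).upper() for k, v in reference.items()}
    out = {}
    for rec in reference:
        out[rec.id] = str(rec.seq).upper()
    return out


def find_motif_occurrences_with_snp(
    reference,
    motif: str,
    snps: list[SnpVariant],
) -> list[MotifOccurrence]:
    """All windows where one SNP allele completes an exact motif match.

    Both strands are scanned.  A matching window containing a second SNP
    is excluded (counted in the log); a SNP whose alleles do not include
    the reference base still yields occurrences but they are flagged.
    """
    seqs = _normalize_reference(reference)
    motif = motif.upper()
    m = len(motif)
    rc_motif = _revcomp(motif)
    snp_by_seq: dict[str, list[SnpVariant]] = {}
    for snp in snps:
        if snp.sequence_id not in seqs:
            raise KeyError(f"unknown sequence {snp.sequence_id!r}")
        if not 0 <= snp.position < len(seqs[snp.sequence_id]):
            raise IndexError(f"SNP position {snp.position} outside {snp.sequence_id!r}")
        snp_by_seq.setdefault(snp.sequence_id, []).append(snp)

    occurrences: list[MotifOccurrence] = []
    n_multi_excluded = 0
    for sid, seq in seqs.items():
        positions_here = sorted(s.position for s in snp_by_seq.get(sid, []))
        for snp in snp_by_seq.get(sid, []):
            a0, a1 = (a.upper() for a in snp.alleles)
            ref_mismatch = seq[snp.position] not in (a0, a1)
            lo = max(0, snp.position - m + 1)
            hi = min(len(seq) - m, snp.position)
            for start in range(lo, hi + 1):
                inside = [p for p in positions_here if start <= p < start + m]
                window = seq[start : start + m]
                off = snp.position - start
                for pres, disr in ((a0, a1), (a1, a0)):
                    cand = window[:off] + pres + window[off + 1 :]
                    for strand, target in (("+", motif), ("-", rc_motif)):
                        if cand != target:
                            continue
                        if len(inside) > 1:
                            n_multi_excluded += 1
                            continue
                        disrupted = window[:off] + disr + window[off + 1 :]
                        snp_offset = off if strand == "+" else m - 1 - off
                        occurrences.append(
                            MotifOccurrence(
                                sequence_id=sid,
                                start=start,
                                strand=strand,
                                motif_text=motif,
                                snp_offset=snp_offset,
                                preserving_allele=pres,
                                disrupting_allele=disr,
                                disrupted_text=disrupted
                                if strand == "+"
                                else _revcomp(disrupted),
                                ref_mismatch=ref_mismatch,
                            )
                        )
    if n_multi_excluded:
        logger.info(
            "find_motif_occurrences_with_snp: excluded %d matching windows "
            "containing more than one SNP",
            n_multi_excluded,
        )
    return occurrences


def snp_flank_sequences(reference, snps: list[SnpVariant], flank: int = 50) -> list[SeqRecord]:
    """Windows of ``2 * flank + 1`` reference bases centered on each SNP.

    Records are truncated (and annotated) at contig ends; ids encode the
    source sequence and position.
    """
    seqs = _normalize_reference(reference)
    records = []
    for snp in snps:
        seq = seqs[snp.sequence_id]
        if not 0 <= snp.position < len(seq):
            raise IndexError(f"SNP position {snp.position} outside {snp.sequence_id!r}")
        lo = max(0, snp.position - flank)
        hi = min(len(seq), snp.position + flank + 1)
        sub = seq[lo:hi]
        truncated = len(sub) < 2 * flank + 1
        rec = SeqRecord(
            Seq(sub),
            id=f"{snp.sequence_id}:{snp.position}",
            description="truncated" if truncated else "",
        )
        rec.annotations["snp_offset"] = snp.position - lo
        rec.annotations["truncated"] = truncated
        records.append(rec)
    return records


def plant_motifs(
    records: list[SeqRecord],
    motif_text: str,
    causal_ids: set[str],
    offset_policy: str = "random",
    seed: int = 0,
) -> list[SeqRecord]:
    """Overwrite ``motif_text`` into each causal record so the span covers
    the record's central (SNP) position; other records pass through
    untouched.  ``offset_policy`` is ``"random"`` (uniform over offsets
    covering the center) or ``"center"``.
    """
    rng = np.random.default_rng(seed)
    m = len(motif_text)
    out = []
    for rec in records:
        if rec.id not in causal_ids:
            out.append(rec)
            continue
        s = str(rec.seq)
        if m >= len(s):
            raise ValueError(f"motif longer than record {rec.id!r}")
        center = rec.annotations.get("snp_offset", len(s) // 2)
        lo = max(0, center - m + 1)
        hi = min(len(s) - m, center)
        if offset_policy == "center":
            start = max(lo, min(hi, center - m // 2))
        else:
            start = int(rng.integers(lo, hi + 1))
        planted = s[:start] + motif_text + s[start + m :]
        new = SeqRecord(Seq(planted), id=rec.id, description=rec.description)
        new.annotations = dict(rec.annotations)
        new.annotations["planted_at"] = start
        out.append(new)
    return out


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T with its supporting sites."""

    probs: np.ndarray  # (w, 4), rows sum to 1
    sites: list[tuple[str, int, str]] = field(default_factory=list)
    score: float = 0.0  # log-likelihood ratio vs 0-order background
    information_content: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (w, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            sites=list(self.sites),
            score=self.score,
            information_content=self.information_content,
        )

    def to_meme_text(self, name: str = "MOTIF_1", background: np.ndarray | None = None) -> str:
        bg = np.full(4, 0.25) if background is None else background
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip(_BASES, bg)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} "
            f"nsites= {max(len(self.sites), 1)} E= 0",
        ]
        for row in self.probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
        return "\n".join(lines)


def _encode_records(records) -> list[np.ndarray]:
    enc = []
    for rec in records:
        s = str(rec.seq).upper() if hasattr(rec, "seq") else str(rec).upper()
        enc.append(np.array([_BASE_INDEX.get(c, 0) for c in s], dtype=np.int8))
    return enc


def _background_freqs(encoded: list[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for e in encoded:
        counts += np.bincount(e, minlength=4)
    freqs = counts / counts.sum()
    return np.clip(freqs, 1e-6, None)


class OopsEm:
    """One-occurrence-per-sequence EM motif finder.

    The latent variable per sequence is the (position, strand) of its
    single motif site (strand scoring optional); the observed-data
    log-likelihood is non-decreasing across iterations.  Starting points
    are softened actual subsequences; ``n_starts`` of them are screened
    by their immediate likelihood and the best ``n_restarts`` are run to
    convergence (the classic two-phase search, which keeps EM out of
    merged-motif optima), with the best final likelihood kept.
    Deterministic given ``seed``.

    After ``fit(records)``: ``pwm_`` (the EM motif), ``loglik_trace_``,
    ``sites_``/``posteriors_`` (per-sequence best site and posterior),
    ``strong_sites_`` and ``site_pwm_`` (sites in the upper cluster of
    best-site scores, and the sharp motif rebuilt from just those —
    what a motif report shows).
    """

    def __init__(
        self,
        width: int,
        n_restarts: int = 3,
        n_starts: int = 30,
        max_iter: int = 100,
        tol: float = 1e-8,
        pseudocount: float = 0.1,
        revcomp: bool = True,
        seed: int = 0,
        background: np.ndarray | None = None,
    ):
        self.width = width
        self.n_restarts = n_restarts
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.pseudocount = pseudocount
        self.revcomp = revcomp
        self.seed = seed
        self.background = background

    def get_params(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "width",
                "n_restarts",
                "n_starts",
                "max_iter",
                "tol",
                "pseudocount",
                "revcomp",
                "seed",
                "background",
            )
        }

    def set_params(self, **params) -> "OopsEm":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- internals ------------------------------------------------------
    def _groups(self, encoded):
        """Group sequences by length; per group stack sliding windows as
        ``(n_group, P, w)`` int8 arrays (plus reverse-complement views)."""
        w = self.width
        by_len: dict[int, list[int]] = {}
        for i, e in enumerate(encoded):
            if e.size < w:
                raise ValueError(f"width {w} exceeds a record of length {e.size}")
            by_len.setdefault(e.size, []).append(i)
        groups = []
        for length, idxs in sorted(by_len.items()):
            mat = np.stack([encoded[i] for i in idxs])
            fwd = np.lib.stride_tricks.sliding_window_view(mat, w, axis=1)
            rc = (3 - fwd[:, :, ::-1]) if self.revcomp else None
            groups.append((np.array(idxs), fwd, rc))
        return groups

    @staticmethod
    def _scores(win, log_ratio):
        # win: (g, P, w) -> (g, P) sums of per-column log ratios
        s = np.zeros(win.shape[:2])
        for i in range(win.shape[2]):
            s += log_ratio[i, win[:, :, i]]
        return s

    def _loglik_and_posteriors(self, groups, log_ratio):
        """E-step: posteriors over (position, strand) per sequence and the
        observed-data log-likelihood (up to the fixed all-background
        constant)."""
        from scipy.special import logsumexp

        total = 0.0
        n_seqs = sum(len(g[0]) for g in groups)
        posts: list = [None] * n_seqs
        for idxs, fwd, rc in groups:
            sf = self._scores(fwd, log_ratio)
            scores = np.concatenate([sf, self._scores(rc, log_ratio)], axis=1) if rc is not None else sf
            lse = logsumexp(scores, axis=1)
            total += float(np.sum(lse - np.log(scores.shape[1])))
            post = np.exp(scores - lse[:, None])
            for row, i in enumerate(idxs):
                posts[i] = post[row]
        return total, posts

    def _m_step(self, groups, posts):
        w = self.width
        counts = np.full((w, 4), self.pseudocount)
        for idxs, fwd, rc in groups:
            P = fwd.shape[1]
            post = np.stack([posts[i] for i in idxs])
            pf = post[:, :P]
            for i in range(w):
                counts[i] += np.bincount(
                    fwd[:, :, i].ravel(), weights=pf.ravel(), minlength=4
                )
            if rc is not None:
                pr = post[:, P:]
                for i in range(w):
                    counts[i] += np.bincount(
                        rc[:, :, i].ravel(), weights=pr.ravel(), minlength=4
                    )
        return counts / counts.sum(axis=1, keepdims=True)

    def _init_pwm(self, encoded, rng):
        """Seed from one randomly chosen subsequence (softened one-hot),
        the classic starting-point strategy for OOPS EM."""
        i = int(rng.integers(0, len(encoded)))
        e = encoded[i]
        pos = int(rng.integers(0, e.size - self.width + 1))
        window = e[pos : pos + self.width]
        probs = np.full((self.width, 4), 0.15)
        probs[np.arange(self.width), window] = 0.55
        return probs

    @staticmethod
    def _bimodal_threshold(scores: np.ndarray) -> float:
        """1-D 2-means split of best-site scores; the upper cluster is
        the motif's supporting site set."""
        c1, c2 = float(scores.min()), float(scores.max())
        if c2 - c1 < 1e-9:
            return c1 - 1.0
        for _ in range(100):
            mid = 0.5 * (c1 + c2)
            lo = scores[scores <= mid]
            hi = scores[scores > mid]
            if lo.size == 0 or hi.size == 0:
                break
            n1, n2 = float(lo.mean()), float(hi.mean())
            if abs(n1 - c1) < 1e-9 and abs(n2 - c2) < 1e-9:
                break
            c1, c2 = n1, n2
        return 0.5 * (c1 + c2)

    # -- fit -------------------------------------------------------------
    def fit(self, records) -> "OopsEm":
        encoded = _encode_records(records)
        if len(encoded) < 2:
            raise ValueError("need at least two records")
        bg = self.background if self.background is not None else _background_freqs(encoded)
        groups = self._groups(encoded)
        ids = [
            rec.id if hasattr(rec, "id") else f"seq_{i}" for i, rec in enumerate(records)
        ]

        # phase 1: screen softened-subsequence starts by immediate loglik
        rng = np.random.default_rng(derive_seed(self.seed, 0))
        n_starts = max(self.n_starts, self.n_restarts)
        screened = []
        for _ in range(n_starts):
            probs = self._init_pwm(encoded, rng)
            log_ratio = np.log(probs) - np.log(bg)[None, :]
            ll0, _ = self._loglik_and_posteriors(groups, log_ratio)
            screened.append((ll0, probs))
        screened.sort(key=lambda t: t[0], reverse=True)

        # phase 2: run EM to convergence from the best starts, then try
        # phase shifts (EM has no shift move, so a start overlapping the
        # motif off-phase converges to a shifted local optimum)
        def run_em(probs):
            trace = []
            prev = -np.inf
            for _ in range(self.max_iter):
                log_ratio = np.log(probs) - np.log(bg)[None, :]
                ll, posts = self._loglik_and_posteriors(groups, log_ratio)
                trace.append(ll)
                probs = self._m_step(groups, posts)
                if ll - prev < self.tol and np.isfinite(prev):
                    break
                prev = ll
            log_ratio = np.log(probs) - np.log(bg)[None, :]
            ll, posts = self._loglik_and_posteriors(groups, log_ratio)
            trace.append(ll)
            return ll, probs, posts, trace

        def shifted(probs, d):
            out = np.tile(bg, (self.width, 1))
            if d > 0:
                out[d:] = probs[:-d]
            else:
                out[:d] = probs[-d:]
            return out

        best = None
        for _ll0, probs in screened[: self.n_restarts]:
            ll, probs, posts, trace = run_em(probs)
            for _round in range(3):
                improved = False
                for d in (1, -1, 2, -2):
                    ll2, p2, posts2, trace2 = run_em(shifted(probs, d))
                    if ll2 > ll + self.tol:
                        ll, probs, posts, trace = ll2, p2, posts2, trace2
                        improved = True
                        break
                if not improved:
                    break
            if best is None or ll > best[0]:
                best = (ll, probs, posts, trace)

        ll, probs, posts, trace = best
        sites = []
        posteriors = []
        n_pos = [e.size - self.width + 1 for e in encoded]
        for i, (sid, post) in enumerate(zip(ids, posts)):
            P = n_pos[i]
            top = int(np.argmax(post))
            strand = "+" if top < P else "-"
            pos = top if top < P else top - P
            sites.append((sid, pos, strand))
            posteriors.append(post)
        ic = float(
            np.sum(probs * (np.log2(np.clip(probs, 1e-12, None)) - np.log2(bg)[None, :]))
        )
        self.background_ = bg
        self.pwm_ = PWM(probs=probs, sites=sites, score=ll, information_content=ic)
        self.loglik_trace_ = np.array(trace)
        self.posteriors_ = posteriors
        self.sites_ = sites

        # supporting-site set: upper cluster of per-sequence best scores,
        # iteratively refined (rebuild from strong sites, rescore)
        w = self.width
        site_probs = probs
        strong_sites: list[tuple[str, int, str]] = []
        best_scores = np.zeros(len(encoded))
        for _refine in range(3):
            log_ratio = np.log(site_probs) - np.log(bg)[None, :]
            best_windows = []
            for i, e in enumerate(encoded):
                win = np.lib.stride_tricks.sliding_window_view(e, w)
                sf = self._scores(win[None], log_ratio)[0]
                score, pos = float(sf.max()), int(sf.argmax())
                window, strand = win[pos], "+"
                if self.revcomp:
                    rc = 3 - win[:, ::-1]
                    sr = self._scores(rc[None], log_ratio)[0]
                    if float(sr.max()) > score:
                        score, pos = float(sr.max()), int(sr.argmax())
                        window, strand = rc[pos], "-"
                best_scores[i] = score
                best_windows.append((ids[i], pos, strand, window))
            thr = self._bimodal_threshold(best_scores)
            strong = np.flatnonzero(best_scores > thr)
            if strong.size == 0:
                strong = np.array([int(np.argmax(best_scores))])
            counts = np.full((w, 4), self.pseudocount)
            strong_sites = []
            for i in strong:
                sid, pos, strand, window = best_windows[i]
                counts[np.arange(w), window] += 1.0
                strong_sites.append((sid, pos, strand))
            site_probs = counts / counts.sum(axis=1, keepdims=True)
        strong_llr = float(np.sum(best_scores[strong]))
        site_ic = float(
            np.sum(
                site_probs
                * (np.log2(np.clip(site_probs, 1e-12, None)) - np.log2(bg)[None, :])
            )
        )
        self.site_scores_ = best_scores
        self.strong_sites_ = strong_sites
        self.site_pwm_ = PWM(
            probs=site_probs,
            sites=strong_sites,
            score=strong_llr,
            information_content=site_ic,
        )
        return self


def oops_em(
    records,
    width: int,
    n_restarts: int = 5,
    seed: int = 0,
    background: np.ndarray | None = None,
    **kwargs,
) -> PWM:
    """Functional wrapper over :class:`OopsEm`; returns the fitted PWM."""
    model = OopsEm(
        width=width, n_restarts=n_restarts, seed=seed, background=background, **kwargs
    )
    model.fit(records)
    return model.pwm_


def discover_motifs(
    records,
    n_motifs: int = 2,
    width_min: int = 10,
    width_max: int = 20,
    min_sites: int = 10,
    n_restarts: int = 3,
    seed: int = 0,
    **em_kwargs,
) -> list[PWM]:
    """Ranked motif discovery: best OOPS-EM fit across the width range by
    a BIC-penalized log-likelihood-ratio score, masking each motif's
    confident sites (posterior > ``site_posterior_min``) with
    background-sampled bases before the next rank.  Motifs supported by
    fewer than ``min_sites`` confident sites are dropped (the list may be
    shorter than ``n_motifs``)."""
    current = [
        SeqRecord(Seq(str(rec.seq) if hasattr(rec, "seq") else str(rec)),
                  id=rec.id if hasattr(rec, "id") else f"seq_{i}")
        for i, rec in enumerate(records)
    ]
    mask_rng = np.random.default_rng(derive_seed(seed, 999))
    found: list[PWM] = []
    for rank in range(n_motifs):
        best_model = None
        best_score = -np.inf
        for width in range(width_min, width_max + 1):
            if width > min(len(r.seq) for r in current):
                continue
            model = OopsEm(
                width=width,
                n_restarts=n_restarts,
                seed=derive_seed(seed, rank, width),
                **em_kwargs,
            ).fit(current)
            # BIC-penalized log-likelihood ratio *per supporting site*:
            # normalizing by the site count measures motif quality rather
            # than coverage, which keeps merged-motif solutions (high
            # total LLR, diluted columns) from outranking sharp motifs
            n_sites_w = max(len(model.strong_sites_), 1)
            score = (
                model.site_pwm_.score - 0.5 * 3 * width * np.log(n_sites_w)
            ) / n_sites_w
            if score > best_score:
                best_score = score
                best_model = model
        if best_model is None:
            break
        id_to_idx = {rec.id: i for i, rec in enumerate(current)}
        if len(best_model.strong_sites_) < min_sites:
            logger.info(
                "discover_motifs: rank %d motif has %d supporting sites (< %d); stopping",
                rank + 1,
                len(best_model.strong_sites_),
                min_sites,
            )
            break
        found.append(best_model.site_pwm_)
        # mask the supporting sites with background-sampled bases
        bg = best_model.background_
        w = best_model.width
        for sid, pos, _strand in best_model.strong_sites_:
            i = id_to_idx[sid]
            s = list(str(current[i].seq))
            repl = mask_rng.choice(4, size=w, p=bg / bg.sum())
            s[pos : pos + w] = [_BASES[b] for b in repl]
            current[i] = SeqRecord(Seq("".join(s)), id=current[i].id)
    return found


def consensus_match(pwm: PWM, consensus: str) -> float:
    """Best mean PWM probability of the consensus bases over all
    full-overlap alignments (both strands); 1.0 for a one-hot encoding of
    the consensus, 0.25 for a uniform PWM."""
    consensus = consensus.upper()
    best = 0.0
    for cand in (pwm, pwm.reverse_complement()):
        w = cand.width
        L = len(consensus)
        k = min(w, L)
        # slide the shorter fully inside the longer
        for off in range(abs(w - L) + 1):
            if w >= L:
                cols = cand.probs[off : off + k]
                bases = consensus
            else:
                cols = cand.probs
                bases = consensus[off : off + k]
            vals = [cols[i, _BASE_INDEX[b]] for i, b in enumerate(bases) if b in _BASE_INDEX]
            if vals:
                best = max(best, float(np.mean(vals)))
    return best
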