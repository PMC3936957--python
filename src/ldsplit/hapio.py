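"""Phased haplotype panels and the LDhat ``sites``/``locs`` text dialect.

A panel is ``n`` phased haplotypes typed at ``L`` biallelic sites with
physical positions.  On disk the panel lives in two files:

* the *sites* file — a ``"n L ploidy"`` header followed by FASTA records
  whose sequence lines are strings over ``0``, ``1`` and ``?`` (missing);
* the *locs* file — a ``"L region_length model"`` header followed by the
  physical positions of the ``L`` sites, conventionally in kb.

Positions are stored in the locs file's native unit (kb by default,
tracked by :attr:`HaplotypePanel.unit`); :attr:`HaplotypePanel.positions_bp`
always exposes base pairs.  Site indices are 0-based everywhere in the API;
file headers use the dialect's counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

__all__ = [
    "HaplotypePanel",
    "MISSING",
    "SitesLocsParseError",
    "PanelValidationError",
    "read_sites_locs",
    "write_sites_locs",
    "maf",
    "cut_window",
]


class SitesLocsParseError(ValueError):
    """Raised when a sites/locs file pair cannot be parsed consistently."""


class PanelValidationError(ValueError):
    """Raised when panel contents violate a structural invariant."""


@dataclass
class HaplotypePanel:
    """``n`` phased haplotypes over ``L`` biallelic sites.

    Parameters
    ----------
    alleles
        ``(n, L)`` int8 matrix with entries 0, 1 or -1 (missing).
    positions
        Length-``L`` strictly increasing physical coordinates in ``unit``.
    labels
        ``n`` unique haplotype identifiers; auto-generated when empty.
    unit
        ``"kb"`` (LDhat-conventional) or ``"bp"``.
    """

    alleles: np.ndarray
    positions: np.ndarray
    labels: list[str] = field(default_factory=list)
    unit: str = "kb"
    ploidy_flag: int = 1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise PanelValidationError("alleles must be a 2-D matrix")
        n, L = self.alleles.shape
        if self.positions.shape != (L,):
            raise PanelValidationError(
                f"positions length {self.positions.shape} != number of sites {L}"
            )
        if L >= 2 and not np.all(np.diff(self.positions) > 0):
            raise PanelValidationError("positions must be strictly increasing")
        if not self.labels:
            self.labels = [f"hap_{i + 1}" for i in range(n)]
        if len(self.labels) != n:
            raise PanelValidationError("labels length must match haplotype count")
        if len(set(self.labels)) != n:
            raise PanelValidationError("labels must be unique")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise PanelValidationError("allele entries must be 0, 1 or missing")
        if self.unit not in ("kb", "bp"):
            raise PanelValidationError(f"unknown position unit {self.unit!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions_bp(self) -> np.ndarray:
        return self.positions * 1000.0 if self.unit == "kb" else self.positions.copy()

    @property
    def positions_kb(self) -> np.ndarray:
        return self.positions.copy() if self.unit == "kb" else self.positions / 1000.0

    def take_rows(self, rows) -> "HaplotypePanel":
        rows = np.asarray(rows, dtype=int)
        return HaplotypePanel(
            alleles=self.alleles[rows].copy(),
            positions=self.positions.copy(),
            labels=[self.labels[i] for i in rows],
            unit=self.unit,
            ploidy_flag=self.ploidy_flag,
        )

    def take_sites(self, sites) -> "HaplotypePanel":
        sites = np.asarray(sites, dtype=int)
        return HaplotypePanel(
            alleles=self.alleles[:, sites].copy(),
            positions=self.positions[sites].copy(),
            labels=list(self.labels),
            unit=self.unit,
            ploidy_flag=self.ploidy_flag,
        )

    def site_index_at_bp(self, position_bp: float) -> int:
        """Index of the site nearest to ``position_bp``."""
        return int(np.argmin(np.abs(self.positions_bp - position_bp)))

    def maf(self, site_index: int) -> float:
        return maf(self, site_index)

    def cut_window(self, center_site: int, half_width: int) -> "HaplotypePanel":
        return cut_window(self, center_site, half_width)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and np.allclose(self.positions, other.positions)
            and self.labels == other.labels
            and self.unit == other.unit
            and self.ploidy_flag == other.ploidy_flag
        )


# -- dialect I/O ---------------------------------------------------------

_ALLELE_CHARS = {"0": 0, "1": 1, "?": MISSING}
_CHAR_FOR_ALLELE = {0: "0", 1: "1", int(MISSING): "?"}


def read_sites_locs(sites_path, locs_path) -> HaplotypePanel:
    """Parse a sites/locs file pair into a :class:`HaplotypePanel`.

    The sites header is ``"n L ploidy"``; the locs header is
    ``"L region_length model_char"`` where the model character (``L`` or
    ``C``) is accepted and ignored.  ``?`` maps to missing.
    """
    sites_path, locs_path = Path(sites_path), Path(locs_path)
    sites_lines = sites_path.read_text().splitlines()
    sites_lines = [ln.rstrip() for ln in sites_lines if ln.strip()]
    if not sites_lines:
        raise SitesLocsParseError(f"{sites_path}: empty sites file")
    header = sites_lines[0].split()
    if len(header) < 2:
        raise SitesLocsParseError(f"{sites_path}: malformed header {sites_lines[0]!r}")
    try:
        n_decl, L_decl = int(header[0]), int(header[1])
        ploidy = int(header[2]) if len(header) > 2 else 1
    except ValueError as exc:
        raise SitesLocsParseError(f"{sites_path}: non-numeric header") from exc

    labels: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    for ln in sites_lines[1:]:
        if ln.startswith(">"):
            if current is not None:
                rows.append("".join(current))
            labels.append(ln[1:].strip())
            current = []
        else:
            if current is None:
                raise SitesLocsParseError(
                    f"{sites_path}: sequence data before first FASTA record"
                )
            current.append(ln.strip())
    if current is not None:
        rows.append("".join(current))

    if len(rows) != n_decl:
        raise SitesLocsParseError(
            f"{sites_path}: header declares {n_decl} haplotypes, found {len(rows)}"
        )
    alleles = np.empty((n_decl, L_decl), dtype=np.int8)
    for i, (label, seq) in enumerate(zip(labels, rows)):
        if len(seq) != L_decl:
            raise SitesLocsParseError(
                f"{sites_path}: record {label!r} has {len(seq)} sites, header says {L_decl}"
            )
        for j, ch in enumerate(seq):
            try:
                alleles[i, j] = _ALLELE_CHARS[ch]
            except KeyError:
                raise SitesLocsParseError(
                    f"{sites_path}: record {label!r} has invalid allele char {ch!r}"
                ) from None

    locs_lines = [ln for ln in locs_path.read_text().splitlines() if ln.strip()]
    if not locs_lines:
        raise SitesLocsParseError(f"{locs_path}: empty locs file")
    lheader = locs_lines[0].split()
    try:
        L_locs = int(lheader[0])
    except (ValueError, IndexError) as exc:
        raise SitesLocsParseError(f"{locs_path}: malformed header") from exc
    body = " ".join(locs_lines[1:]).split()
    if len(body) != L_locs:
        raise SitesLocsParseError(
            f"{locs_path}: header declares {L_locs} positions, found {len(body)}"
        )
    if L_locs != L_decl:
        raise SitesLocsParseError(
            f"sites file declares {L_decl} sites but locs file declares {L_locs}"
        )
    positions = np.array([float(x) for x in body])
    if L_locs >= 2 and not np.all(np.diff(positions) > 0):
        raise PanelValidationError(f"{locs_path}: positions are not strictly increasing")
    return HaplotypePanel(
        alleles=alleles, positions=positions, labels=labels, ploidy_flag=ploidy
    )


def write_sites_locs(panel: HaplotypePanel, sites_path, locs_path) -> None:
    """Write ``panel`` in the sites/locs dialect (inverse of the reader)."""
    sites_path, locs_path = Path(sites_path), Path(locs_path)
    n, L = panel.alleles.shape
    out = [f"{n} {L} {panel.ploidy_flag}"]
    for label, row in zip(panel.labels, panel.alleles):
        out.append(f">{label}")
        out.append("".join(_CHAR_FOR_ALLELE[int(a)] for a in row))
    sites_path.write_text("\n".join(out) + "\n")

    span = panel.positions[-1] - panel.positions[0] if L else 0.0
    lout = [f"{L} {_fmt(span + panel.positions[0])} L"]
    lout.extend(_fmt(p) for p in panel.positions)
    locs_path.write_text("\n".join(lout) + "\n")


def _fmt(x: float) -> str:
    s = f"{x:.12g}"
    return s if s else "0"


# -- site-level helpers ---------------------------------------------------

def maf(panel: HaplotypePanel, site_index: int) -> float:
    """Minor allele frequency at ``site_index`` over non-missing calls."""
    col = panel.alleles[:, site_index]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise PanelValidationError(f"site {site_index}: all calls missing, MAF undefined")
    f1 = float(np.mean(obs == 1))
    return min(f1, 1.0 - f1)


def cut_window(panel: HaplotypePanel, center_site: int, half_width: int) -> HaplotypePanel:
    """Sub-panel of up to ``2*half_width + 1`` sites around ``center_site``.

    Truncated silently (but logged) at the panel edges; positions and
    relative order are preserved.
    """
    if not 0 <= center_site < panel.n_sites:
        raise IndexError(f"center_site {center_site} out of range")
    lo = max(0, center_site - half_width)
    hi = min(panel.n_sites, center_site + half_width + 1)
    if hi - lo < 2 * half_width + 1:
        logger.info(
            "cut_window truncated at panel edge: requested %d sites, got %d",
            2 * half_width + 1,
            hi - lo,
        )
    return panel.take_sites(np.arange(lo, hi))
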