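"""Sequence analytics for Nup98-style FG domains.

FG domains are intrinsically disordered nucleoporin regions built from
phenylalanine-glycine (FG) dipeptide motifs separated by low-complexity
spacers.  This module locates FG dipeptides, classifies them into the
context-defined motif taxonomy used in the field (GLFG, SLFG, PAFG, GFGQ,
PFG, (G/A)FG, (S/T)FG, other), computes per-100-residue motif densities,
amino-acid composition profiles (full domain, domain without the GLEBS
insertion, or spacers only), charge/hydropathy coordinates on a rescaled
octanol-water scale, and cohort summary statistics.

Coordinates are 1-based inclusive residue intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = set(STANDARD_AA) | {"X"}

CHARGED = set("DEKR")
FILVM = set("FILVM")
FILVMP = set("FILVMP")

#: Octanol/water partitioning hydrophobicities of N-alpha-acetyl amino acid
#: amides, linearly rescaled to [0, 1] (R = 0, W = 1).
DEFAULT_HYDROPHOBICITY = {
    "R": 0.0, "K": 0.006, "D": 0.012, "E": 0.113, "N": 0.132,
    "Q": 0.242, "S": 0.298, "G": 0.31, "H": 0.35, "T": 0.39,
    "A": 0.405, "P": 0.46, "Y": 0.604, "V": 0.684, "M": 0.687,
    "C": 0.782, "L": 0.831, "F": 0.859, "I": 0.862, "W": 1.0,
}

MOTIF_CLASS_NAMES = (
    "GFGQ", "GLFG", "SLFG", "PAFG", "PFG", "(G/A)FG", "(S/T)FG", "other FG",
)


class SequenceError(ValueError):
    """Raised for invalid residue strings or empty regions."""


def validate_residues(seq: str) -> str:
    """Upper-case ``seq`` and reject characters outside the 20 letters + X."""
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_LETTERS:
            raise SequenceError(
                f"invalid residue {ch!r} at position {i + 1} (1-based)"
            )
    return seq


@dataclass
class FGDomainRecord:
    """A protein sequence with FG-domain boundaries.

    ``glebs_interval`` is the 1-based inclusive interval of an embedded
    Gle2/Rae1-binding (GLEBS) segment, which is excluded from composition
    and charge/hydropathy statistics but not from motif counting.
    """

    id: str
    residues: str
    organism: str = ""
    glebs_interval: tuple[int, int] | None = None
    source: str = "user"
    length_ok: bool | None = None

    def __post_init__(self) -> None:
        self.residues = validate_residues(self.residues)
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.glebs_interval is not None:
            lo, hi = self.glebs_interval
            if not (1 <= lo <= hi <= len(self.residues)):
                raise SequenceError(
                    f"record {self.id!r}: GLEBS interval {lo}-{hi} outside "
                    f"[1, {len(self.residues)}]"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def residues_without_glebs(self) -> str:
        if self.glebs_interval is None:
            return self.residues
        lo, hi = self.glebs_interval
        return self.residues[: lo - 1] + self.residues[hi:]


@dataclass(frozen=True)
class MotifClass:
    """One context-defined FG motif class.

    ``prev2``: exact two residues preceding the FG dipeptide;
    ``prev1``: allowed single residues immediately preceding it;
    ``suffix``: required residue following the FG dipeptide.
    The full matched span (for spacer masking) extends ``left_extent``
    residues before the F and ``right_extent`` after the G.
    """

    name: str
    rank: int
    prev2: str | None = None
    prev1: str | None = None
    suffix: str | None = None
    left_extent: int = 0
    right_extent: int = 0

    def matches(self, seq: str, p0: int) -> bool:
        """True if the FG dipeptide at 0-based index ``p0`` is this class."""
        if self.prev2 is not None:
            if p0 < 2 or seq[p0 - 2 : p0] != self.prev2:
                return False
        if self.prev1 is not None:
            if p0 < 1 or seq[p0 - 1] not in self.prev1:
                return False
        if self.suffix is not None:
            if p0 + 2 >= len(seq) or seq[p0 + 2] != self.suffix:
                return False
        return True


@dataclass(frozen=True)
class MotifCatalog:
    """Ordered FG motif taxonomy; lower rank wins.

    Longer, more specific context outranks shorter context, so e.g. a
    PAFG occurrence is never double-counted as (G/A)FG and a GFGQ never
    as (G/A)FG.  The final class is a catch-all, so the classes always
    partition the set of FG dipeptides.
    """

    classes: tuple[MotifClass, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if sorted(names) != sorted(MOTIF_CLASS_NAMES):
            raise ValueError(f"catalog classes {names} must cover "
                             f"{MOTIF_CLASS_NAMES}")
        ranks = [c.rank for c in self.classes]
        if len(set(ranks)) != len(ranks):
            raise ValueError("precedence ranks must be unique")

    def ordered(self) -> list[MotifClass]:
        return sorted(self.classes, key=lambda c: c.rank)

    def classify_position(self, seq: str, p0: int) -> MotifClass:
        for cls in self.ordered():
            if cls.matches(seq, p0):
                return cls
        raise AssertionError("catch-all class missing")  # pragma: no cover


DEFAULT_CATALOG = MotifCatalog(classes=(
    MotifClass("GFGQ", 0, prev1="G", suffix="Q", left_extent=1, right_extent=1),
    MotifClass("GLFG", 1, prev2="GL", left_extent=2),
    MotifClass("SLFG", 2, prev2="SL", left_extent=2),
    MotifClass("PAFG", 3, prev2="PA", left_extent=2),
    MotifClass("PFG", 4, prev1="P", left_extent=1),
    MotifClass("(G/A)FG", 5, prev1="GA", left_extent=1),
    MotifClass("(S/T)FG", 6, prev1="ST", left_extent=1),
    MotifClass("other FG", 7),
))


@dataclass
class MotifCounts:
    counts: dict[str, int]
    total_fg: int
    domain_length: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_fg:
            raise ValueError("class counts must partition total_fg")
        if self.total_fg > self.domain_length // 2:
            raise ValueError("more FG motifs than length permits")


def find_fg_dipeptides(seq: str) -> list[int]:
    """1-based start positions of every FG dipeptide in ``seq``.

    FG dipeptides are distinct 2-mers (an F followed by a G), so
    occurrences never overlap; ``"FGFG"`` yields [1, 3].
    """
    seq = validate_residues(seq)
    return [i + 1 for i in range(len(seq) - 1)
            if seq[i] == "F" and seq[i + 1] == "G"]


def classify_fg_motifs(
    record: FGDomainRecord, catalog: MotifCatalog = DEFAULT_CATALOG
) -> MotifCounts:
    """Assign every FG dipeptide of the full domain to exactly one class.

    Motif counting runs on the full domain including any GLEBS interval
    (the GLEBS is masked only for composition/spacer statistics), which
    is what keeps published motif counts and densities consistent.
    """
    seq = record.residues
    counts = {name: 0 for name in MOTIF_CLASS_NAMES}
    for pos in find_fg_dipeptides(seq):
        cls = catalog.classify_position(seq, pos - 1)
        counts[cls.name] += 1
    return MotifCounts(counts=counts, total_fg=sum(counts.values()),
                       domain_length=len(seq))


def motif_spans(
    record: FGDomainRecord,
    catalog: MotifCatalog = DEFAULT_CATALOG,
    full_context: bool = True,
) -> list[tuple[int, int]]:
    """1-based inclusive spans covered by classified motifs.

    With ``full_context`` (default) each motif occupies its full matched
    span (4 residues for GLFG-type or GFGQ, 3 for PFG-type, 2 for a bare
    FG); otherwise only the FG dipeptide itself.
    """
    seq = record.residues
    spans = []
    for pos in find_fg_dipeptides(seq):
        if full_context:
            cls = catalog.classify_position(seq, pos - 1)
            lo = pos - cls.left_extent
            hi = pos + 1 + cls.right_extent
        else:
            lo, hi = pos, pos + 1
        spans.append((max(1, lo), min(len(seq), hi)))
    return spans


@dataclass
class CompositionProfile:
    region: str
    n_residues: int
    fractions: dict[str, float]
    nq_content: float
    charged_fraction: float
    filvm_fraction: float
    filvmp_fraction: float


def _region_residues(
    record: FGDomainRecord,
    region: str,
    catalog: MotifCatalog = DEFAULT_CATALOG,
    full_context_spacers: bool = True,
) -> str:
    n = record.length
    masked = np.zeros(n, dtype=bool)
    if region not in ("full_domain", "domain_wo_glebs", "spacers"):
        raise ValueError(f"unknown region {region!r}")
    if region in ("domain_wo_glebs", "spacers") and record.glebs_interval:
        lo, hi = record.glebs_interval
        masked[lo - 1 : hi] = True
    if region == "spacers":
        for lo, hi in motif_spans(record, catalog, full_context_spacers):
            masked[lo - 1 : hi] = True
    return "".join(ch for ch, m in zip(record.residues, masked) if not m)


def composition_profile(
    record: FGDomainRecord,
    region: str = "full_domain",
    catalog: MotifCatalog = DEFAULT_CATALOG,
    full_context_spacers: bool = True,
) -> CompositionProfile:
    """Residue composition of a domain region.

    Region ``spacers`` removes the GLEBS interval and every classified
    motif span; ``domain_wo_glebs`` removes only the GLEBS.  Residues
    'X' are excluded from both numerator and denominator.
    """
    residues = _region_residues(record, region, catalog, full_context_spacers)
    counted = [ch for ch in residues if ch != "X"]
    if not counted:
        raise SequenceError(f"no residues in region {region!r}")
    n = len(counted)
    fractions = {aa: counted.count(aa) / n for aa in STANDARD_AA}
    return CompositionProfile(
        region=region,
        n_residues=n,
        fractions=fractions,
        nq_content=sum(fractions[a] for a in "NQ"),
        charged_fraction=sum(fractions[a] for a in CHARGED),
        filvm_fraction=sum(fractions[a] for a in FILVM),
        filvmp_fraction=sum(fractions[a] for a in FILVMP),
    )


def motif_density(counts: MotifCounts) -> dict[str, float]:
    """Per-class occurrences per 100 residues of full domain length.

    The denominator is the full FG-domain length including any GLEBS
    interval.  Values are raw; round to one decimal for report columns.
    """
    if counts.domain_length <= 0:
        raise ValueError("domain_length must be positive")
    dens = {name: 100.0 * c / counts.domain_length
            for name, c in counts.counts.items()}
    dens["All FG dipeptides"] = 100.0 * counts.total_fg / counts.domain_length
    return dens


def mean_hydrophobicity(
    seq: str, scale: dict[str, float] | None = None
) -> float:
    """Arithmetic mean of per-residue hydrophobicities; X excluded."""
    scale = DEFAULT_HYDROPHOBICITY if scale is None else scale
    seq = validate_residues(seq)
    vals = [scale[ch] for ch in seq if ch != "X"]
    if not vals:
        raise SequenceError("no scorable residues (all X or empty)")
    return float(np.mean(vals))


@dataclass(frozen=True)
class ChargeHydropathyPoint:
    id: str
    charged_fraction: float
    mean_hydrophobicity: float

    def __post_init__(self) -> None:
        if not (0 <= self.charged_fraction <= 1
                and 0 <= self.mean_hydrophobicity <= 1):
            raise ValueError("coordinates must lie in [0, 1]")


def charge_hydropathy_point(
    record: FGDomainRecord, scale: dict[str, float] | None = None
) -> ChargeHydropathyPoint:
    """Charged fraction (D+E+K+R over length) and mean hydrophobicity.

    For FG domains the GLEBS interval is excluded before either
    statistic is computed.
    """
    seq = record.residues_without_glebs()
    counted = [ch for ch in seq if ch != "X"]
    if not counted:
        raise SequenceError("no scorable residues")
    charged = sum(1 for ch in counted if ch in CHARGED)
    return ChargeHydropathyPoint(
        id=record.id,
        charged_fraction=charged / len(counted),
        mean_hydrophobicity=mean_hydrophobicity("".join(counted), scale),
    )


def delimit_fg_domain(
    full_sequence: str,
    record_id: str = "domain",
    glebs_interval: tuple[int, int] | None = None,
    organism: str = "",
    min_len: int = 400,
    max_len: int = 1000,
    source: str = "user",
) -> FGDomainRecord:
    """Cut the FG domain: residues 1 through the last FG dipeptide.

    The domain runs from the translation start up to and including the G
    of the last FG dipeptide.  ``length_ok`` flags whether the domain
    falls in the [min_len, max_len] residue window used for cohort
    statistics (default 400-1000).
    """
    seq = validate_residues(full_sequence)
    positions = find_fg_dipeptides(seq)
    if not positions:
        raise SequenceError(f"{record_id!r}: not an FG domain (no FG dipeptide)")
    end = positions[-1] + 1  # include the G
    domain = seq[:end]
    glebs = None
    if glebs_interval is not None:
        lo, hi = glebs_interval
        if lo <= end:
            glebs = (lo, min(hi, end))
    rec = FGDomainRecord(id=record_id, residues=domain, organism=organism,
                         glebs_interval=glebs, source=source)
    rec.length_ok = min_len <= rec.length <= max_len
    return rec


@dataclass
class CohortSummary:
    """Medians and dispersions of per-domain FG statistics.

    Dispersion is reported as both the median absolute deviation (MAD)
    and the population standard deviation; published "median +/- x"
    figures do not state which estimator they use, so both are given.
    """

    n_domains: int
    median_fg_motifs: float
    mad_fg_motifs: float
    sd_fg_motifs: float
    median_residues_per_fg: float
    mad_residues_per_fg: float
    sd_residues_per_fg: float
    median_length: float
    mad_length: float
    sd_length: float


def _med_mad_sd(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    sd = float(np.std(arr))
    return med, mad, sd


def cohort_summary(
    records: Iterable[FGDomainRecord],
    catalog: MotifCatalog = DEFAULT_CATALOG,
    enforce_length_filter: bool = True,
) -> CohortSummary:
    """Summarise motif counts, residues-per-motif, and lengths of a cohort."""
    recs = list(records)
    if enforce_length_filter:
        recs = [r for r in recs if r.length_ok is not False]
    if not recs:
        raise SequenceError("empty cohort")
    n_motifs, res_per_fg, lengths = [], [], []
    for rec in recs:
        mc = classify_fg_motifs(rec, catalog)
        if mc.total_fg == 0:
            raise SequenceError(f"{rec.id!r}: no FG motifs")
        n_motifs.append(mc.total_fg)
        res_per_fg.append(rec.length / mc.total_fg)
        lengths.append(rec.length)
    m1 = _med_mad_sd(n_motifs)
    m2 = _med_mad_sd(res_per_fg)
    m3 = _med_mad_sd(lengths)
    return CohortSummary(len(recs), *m1, *m2, *m3)


def molecular_weight(seq: str) -> float:
    """Average molecular mass of the polypeptide in kDa.

    Sum of average residue masses plus one water; 'X' is rejected
    (exclude unknown residues before calling).
    """
    seq = validate_residues(seq)
    if not seq:
        raise SequenceError("empty sequence")
    if "X" in seq:
        raise SequenceError(
            "sequence contains 'X'; remove unknown residues before "
            "computing molecular weight"
        )
    return _bio_mw(seq, seq_type="protein", monoisotopic=False) / 1000.0


def heatmap_bins(
    points: Iterable[ChargeHydropathyPoint] | np.ndarray, n_bins: int
) -> np.ndarray:
    """2-D occupancy grid of charge/hydropathy points on [0,1]x[0,1].

    Bins are half-open [lo, hi) with the last bin closed, so boundary
    points at exactly 1.0 are counted.  Axis 0 is charged fraction,
    axis 1 mean hydrophobicity.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pts = list(points)
    if pts and isinstance(pts[0], ChargeHydropathyPoint):
        xy = np.array([(p.charged_fraction, p.mean_hydrophobicity)
                       for p in pts], dtype=float)
    else:
        xy = np.asarray(pts, dtype=float).reshape(-1, 2)
    if xy.size and ((xy < 0).any() or (xy > 1).any()):
        raise ValueError("point outside [0,1]x[0,1]")
    if not xy.size:
        return np.zeros((n_bins, n_bins), dtype=int)
    grid, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=n_bins,
                                range=[[0, 1], [0, 1]])
    return grid.astype(int)
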