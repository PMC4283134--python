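"""Seeded generators emulating every input the analysis pipeline consumes.

These generators produce FG-domain-like sequences with a known motif
content, charge/hydropathy clouds for IDP-like, globular-like and FG-like
cohorts, fluorescence calibration series for the ratiometric concentration
estimator, and phase-separation titrations with a planted critical
concentration.  Each generator is deterministic under its seed and returns
the planted ground truth alongside the data, so parameter recovery can be
tested end to end without any external download.

Distribution families are Normals clipped to their valid ranges: published
cohort figures give only a centre and a spread, so this is an emulation of
summary statistics, not an inference of the real underlying distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import CalibrationSeries, TitrationSeries
from .sequence import (
    DEFAULT_CATALOG,
    FGDomainRecord,
    MOTIF_CLASS_NAMES,
    MotifCatalog,
    classify_fg_motifs,
)

# Spacer composition loosely modelled on the low-complexity spacers of
# Nup98-type FG domains: dominated by T, S, G, A, N, Q and P, nearly
# charge-free (about 2.5% D+E+K+R) and free of F (so spacers cannot spawn
# spurious FG dipeptides).
DEFAULT_SPACER_COMPOSITION = {
    "T": 0.175, "S": 0.155, "G": 0.13, "A": 0.11, "N": 0.125, "Q": 0.09,
    "P": 0.06, "L": 0.03, "V": 0.025, "I": 0.015, "M": 0.015, "H": 0.02,
    "Y": 0.015, "W": 0.005, "C": 0.005, "K": 0.012, "R": 0.008,
    "E": 0.003, "D": 0.002, "F": 0.0,
}

# Motif-class mixture loosely modelled on a GLFG/SLFG-dominated fungal
# Nup98 paralog.
DEFAULT_MOTIF_MIXTURE = {
    "GFGQ": 0.0, "GLFG": 0.26, "SLFG": 0.26, "PAFG": 0.0, "PFG": 0.07,
    "(G/A)FG": 0.10, "(S/T)FG": 0.16, "other FG": 0.15,
}

_MOTIF_MIN_SPAN = 2  # a bare FG dipeptide

# GLEBS-like inserts are markedly more charged than FG spacers.
_GLEBS_COMPOSITION = {
    "E": 0.15, "K": 0.14, "D": 0.06, "R": 0.05, "N": 0.10, "S": 0.10,
    "T": 0.10, "L": 0.10, "I": 0.05, "A": 0.10, "Q": 0.05,
}

# Residues that leave an FG dipeptide in the catch-all class when placed
# directly before it (no single- or two-residue context rule fires).  Q is
# excluded so that no motif string starts with Q, which could upgrade an
# immediately preceding GFG to GFGQ.
_OTHER_FG_PREFIXES = "NHVMIWCYDEKR"


@dataclass
class SequenceGeneratorSpec:
    """Parameters of the FG-domain sequence generator.

    Lengths are drawn from a Normal(length_median, length_spread) clipped
    to [length_min, length_max]; the number of planted FG motifs per
    domain is round(density * length / 100).
    """

    n_domains: int = 10
    length_median: float = 549.0
    length_spread: float = 87.0
    length_min: int = 400
    length_max: int = 1000
    fg_density_per_100aa: float = 8.0
    motif_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_MIXTURE))
    spacer_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_COMPOSITION))
    glebs_length: int = 0
    glebs_position: int | None = None  # 1-based start; None = mid-domain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 0:
            raise ValueError("n_domains must be >= 0")
        mix_sum = sum(self.motif_mixture.values())
        if self.fg_density_per_100aa > 0 and abs(mix_sum - 1.0) > 1e-9:
            raise ValueError("motif mixture must sum to 1")
        if set(self.motif_mixture) - set(MOTIF_CLASS_NAMES):
            raise ValueError("unknown motif class in mixture")
        if abs(sum(self.spacer_composition.values()) - 1.0) > 1e-9:
            raise ValueError("spacer composition must sum to 1")
        if self.fg_density_per_100aa > 100.0 / _MOTIF_MIN_SPAN:
            raise ValueError("infeasible FG density")
        if self.fg_density_per_100aa < 0:
            raise ValueError("density must be >= 0")


def _sample_letters(rng: np.random.Generator, comp: dict[str, float],
                    n: int) -> list[str]:
    letters = list(comp)
    probs = np.array([comp[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(letters, size=n, p=probs))


def _motif_string(rng: np.random.Generator, cls: str,
                  spacer_comp: dict[str, float]) -> str:
    if cls in ("GFGQ", "GLFG", "SLFG", "PAFG"):
        return cls
    if cls == "PFG":
        return "PFG"
    if cls == "(G/A)FG":
        return rng.choice(["G", "A"]) + "FG"
    if cls == "(S/T)FG":
        return rng.choice(["S", "T"]) + "FG"
    # catch-all: pick a neutral prefix, weighted by the spacer composition
    weights = np.array([spacer_comp.get(a, 0.0) for a in _OTHER_FG_PREFIXES])
    if weights.sum() <= 0:
        weights = np.ones(len(_OTHER_FG_PREFIXES))
    weights = weights / weights.sum()
    return rng.choice(list(_OTHER_FG_PREFIXES), p=weights) + "FG"


def _build_domain(rng: np.random.Generator, spec: SequenceGeneratorSpec,
                  length: int) -> tuple[str, list[str]]:
    """Assemble one sequence of exactly ``length`` residues.

    Returns (sequence, planted class list).  Junction guards ensure a
    planted motif cannot be re-classified by its flanking spacer letters
    (e.g. a spacer 'P' directly before an AFG would turn it into PAFG).
    """
    n_fg = int(round(spec.fg_density_per_100aa * length / 100.0))
    classes = []
    if n_fg > 0:
        names = list(spec.motif_mixture)
        probs = np.array([spec.motif_mixture[c] for c in names], dtype=float)
        probs = probs / probs.sum()
        classes = list(rng.choice(names, size=n_fg, p=probs))
    motifs = [_motif_string(rng, c, spec.spacer_composition) for c in classes]
    budget = length - sum(len(m) for m in motifs)
    if budget < 0:
        raise ValueError("infeasible FG density for drawn length")
    # split the spacer budget over n_fg + 1 gaps
    cuts = np.sort(rng.integers(0, budget + 1, size=n_fg)) if n_fg else []
    gaps = np.diff(np.concatenate([[0], cuts, [budget]])).astype(int)

    parts: list[str] = []
    for i, gap in enumerate(gaps):
        spacer = _sample_letters(rng, spec.spacer_composition, int(gap))
        # no spurious FG inside or across the spacer
        prev = parts[-1][-1] if parts and parts[-1] else ""
        for j in range(len(spacer)):
            left = spacer[j - 1] if j else prev
            while spacer[j] == "G" and left == "F":
                spacer[j] = _sample_letters(
                    rng, spec.spacer_composition, 1)[0]
        nxt_motif = motifs[i] if i < len(motifs) else ""
        if spacer and nxt_motif:
            # junction guards: P+AFG -> PAFG, G/S+LFG upgrades, F+G...
            bad = {"AFG": "P"}.get(nxt_motif, "")
            while spacer[-1] in bad + "F":
                spacer[-1] = _sample_letters(
                    rng, spec.spacer_composition, 1)[0]
        if i > 0 and motifs[i - 1] == "GFG" and spacer:
            while spacer[0] == "Q":
                spacer[0] = _sample_letters(
                    rng, spec.spacer_composition, 1)[0]
        parts.append("".join(spacer))
        if nxt_motif:
            parts.append(nxt_motif)
    seq = "".join(parts)
    assert len(seq) == length
    return seq, classes


@dataclass
class SyntheticCohort:
    records: list[FGDomainRecord]
    ledger: pd.DataFrame
    spec: SequenceGeneratorSpec


def generate_fg_domains(
    spec: SequenceGeneratorSpec,
    catalog: MotifCatalog = DEFAULT_CATALOG,
) -> SyntheticCohort:
    """Generate FG-domain-like sequences with a known motif ledger.

    The ledger holds, per record, the planted per-class motif counts and
    the realised FG density; generated sequences are verified against
    the motif classifier, so planted and classified counts agree by
    construction.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records, rows = [], []
    for i in range(spec.n_domains):
        length = int(np.clip(
            round(rng.normal(spec.length_median, spec.length_spread)),
            spec.length_min, spec.length_max))
        seq, classes = _build_domain(rng, spec, length)
        glebs = None
        if spec.glebs_length > 0:
            start = (spec.glebs_position if spec.glebs_position is not None
                     else length // 2)
            insert = "".join(
                _sample_letters(rng, _GLEBS_COMPOSITION, spec.glebs_length))
            seq = seq[: start - 1] + insert + seq[start - 1:]
            glebs = (start, start + spec.glebs_length - 1)
        rec = FGDomainRecord(
            id=f"synth_{i:04d}", residues=seq, organism="synthetic",
            glebs_interval=glebs, source="synthetic")
        rec.length_ok = spec.length_min <= rec.length <= spec.length_max
        # verify the planted annotation against the classifier
        observed = classify_fg_motifs(rec, catalog)
        planted = {name: classes.count(name) for name in MOTIF_CLASS_NAMES}
        if spec.glebs_length == 0 and observed.counts != planted:
            raise AssertionError(
                f"planted/classified motif mismatch in {rec.id}: "
                f"{planted} vs {observed.counts}")
        row = {"id": rec.id, "length": rec.length,
               "n_fg": observed.total_fg,
               "density_per_100aa": 100.0 * observed.total_fg / rec.length}
        row.update({f"n_{name}": planted[name] for name in MOTIF_CLASS_NAMES})
        rows.append(row)
        records.append(rec)
    ledger = pd.DataFrame(rows)
    return SyntheticCohort(records=records, ledger=ledger, spec=spec)


#: Default cohort parameters (charged-fraction mean/sd, hydrophobicity
#: mean/sd).  FG-like domains are nearly charge-free (2.5 +/- 0.4 %) and
#: about as hydrophobic as globular proteins; IDP-like regions are highly
#: charged (28 +/- 7 %) and less hydrophobic; globular proteins sit at
#: 24 +/- 3 % charged.
CLOUD_COHORTS = {
    "idp_like": (0.28, 0.07, 0.40, 0.06),
    "globular_like": (0.24, 0.03, 0.47, 0.04),
    "fg_like": (0.025, 0.004, 0.46, 0.03),
}


@dataclass
class CloudGeneratorSpec:
    cohort: str = "fg_like"
    n: int = 1000
    charged_mean: float | None = None
    charged_sd: float | None = None
    hydro_mean: float | None = None
    hydro_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in CLOUD_COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        defaults = CLOUD_COHORTS[self.cohort]
        if self.charged_mean is None:
            self.charged_mean = defaults[0]
        if self.charged_sd is None:
            self.charged_sd = defaults[1]
        if self.hydro_mean is None:
            self.hydro_mean = defaults[2]
        if self.hydro_sd is None:
            self.hydro_sd = defaults[3]
        if self.charged_sd < 0 or self.hydro_sd < 0:
            raise ValueError("spreads must be >= 0")


def generate_cloud(spec: CloudGeneratorSpec) -> np.ndarray:
    """Charge/hydropathy points for a synthetic cohort.

    Returns an (n, 2) array of (charged_fraction, mean_hydrophobicity),
    drawn from clipped Normals with the cohort's parameters.
    """
    rng = np.random.default_rng(spec.seed)
    charged = np.clip(rng.normal(spec.charged_mean, spec.charged_sd, spec.n),
                      0.0, 1.0)
    hydro = np.clip(rng.normal(spec.hydro_mean, spec.hydro_sd, spec.n),
                    0.0, 1.0)
    return np.column_stack([charged, hydro]) if spec.n else \
        np.empty((0, 2))


def generate_calibration(
    true_concentration_molar: float,
    labeled_fraction: float = 1.0 / 714.0,
    slope: float = 10.0e6,
    noise_sd: float = 0.0,
    n_standards: int = 10,
    seed: int = 0,
    standard_concentrations: np.ndarray | None = None,
) -> CalibrationSeries:
    """Emulate a ratiometric fluorescence calibration experiment.

    Standards of known concentration receive signal slope*c perturbed by
    relative Gaussian noise ``noise_sd``; the intra-particle signal
    reports the labelled fraction of the true total concentration with
    the same relative noise.  Inverting with zero noise recovers
    ``true_concentration_molar`` exactly.
    """
    if true_concentration_molar < 0 or noise_sd < 0:
        raise ValueError("inputs must be >= 0")
    rng = np.random.default_rng(seed)
    if standard_concentrations is None:
        standard_concentrations = np.linspace(0.5e-6, 10e-6, n_standards)
    conc = np.asarray(standard_concentrations, dtype=float)
    sig = slope * conc * (1.0 + rng.normal(0.0, noise_sd, conc.size))
    sig = np.maximum(sig, 0.0)
    intra = (slope * true_concentration_molar * labeled_fraction
             * (1.0 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)))
    return CalibrationSeries(
        standards=list(zip(conc.tolist(), sig.tolist())),
        intra_signal=float(max(intra, 0.0)),
        labeled_fraction=labeled_fraction,
    )


def generate_titration(
    c_crit_molar: float,
    totals_molar,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Emulate a phase-separation titration with a planted critical point.

    Below the critical concentration everything stays soluble; above it
    the soluble (monomer) pool sits at the critical concentration, with
    optional relative Gaussian noise, clipped to [0, total].
    """
    if c_crit_molar <= 0:
        raise ValueError("c_crit must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for total in np.asarray(totals_molar, dtype=float):
        soluble = min(total, c_crit_molar)
        if noise_sd:
            soluble *= 1.0 + rng.normal(0.0, noise_sd)
        soluble = float(np.clip(soluble, 0.0, total))
        points.append((float(total), soluble))
    return TitrationSeries(points=points, method="pellet_supernatant")
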