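"""Report tables and pipeline orchestration.

Renders per-domain profile tables (length, molecular weight, motif counts
and densities, composition fractions, charge/hydropathy coordinates, spacer
composition) as pandas DataFrames with fixed column names, writes TSV/JSON
mirrors, and runs the full multi-stage pipeline from a single config.

Report conventions: residue intervals are 1-based inclusive; densities and
composition percentages are rounded to one decimal in the TSV output while
JSON mirrors keep full precision; molecular weights are in kDa.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .biophysics import (
    CalibrationSeries,
    MolecularSpecies,
    NPCGeometry,
    critical_concentration,
    npc_local_concentration,
    ratiometric_intra_concentration,
)
from .io import read_fasta, write_fasta
from .sequence import (
    DEFAULT_CATALOG,
    FGDomainRecord,
    MOTIF_CLASS_NAMES,
    MotifCatalog,
    SequenceError,
    charge_hydropathy_point,
    classify_fg_motifs,
    composition_profile,
    heatmap_bins,
    molecular_weight,
    motif_density,
)
from .synth import (
    CloudGeneratorSpec,
    SequenceGeneratorSpec,
    generate_calibration,
    generate_cloud,
    generate_fg_domains,
    generate_titration,
)
from .transport import TransportParams, sensitivity_analysis, simulate

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def profile_records(
    records: list[FGDomainRecord],
    catalog: MotifCatalog = DEFAULT_CATALOG,
    min_len: int | None = None,
    max_len: int | None = None,
) -> pd.DataFrame:
    """One row per FG domain with every sequence-derived descriptor.

    Motif counts and densities are computed on the full domain (GLEBS
    included); composition and charge/hydropathy statistics exclude the
    GLEBS interval; spacer composition additionally excludes the full
    matched motif spans.  Rows keep the input order.
    """
    rows = []
    for rec in records:
        if min_len is not None and rec.length < min_len:
            continue
        if max_len is not None and rec.length > max_len:
            continue
        counts = classify_fg_motifs(rec, catalog)
        dens = motif_density(counts)
        try:
            mw = molecular_weight(rec.residues)
        except SequenceError:
            mw = np.nan
        full = composition_profile(rec, "full_domain", catalog)
        wo_glebs = composition_profile(rec, "domain_wo_glebs", catalog)
        row: dict[str, Any] = {
            "id": rec.id,
            "organism": rec.organism,
            "length": rec.length,
            "mw_kda": mw,
            "n_fg_total": counts.total_fg,
            "density_all_fg_per_100aa": dens["All FG dipeptides"],
            "nq_content_pct": 100.0 * full.nq_content,
            "charged_pct_wo_glebs": 100.0 * wo_glebs.charged_fraction,
            "filvm_pct_wo_glebs": 100.0 * wo_glebs.filvm_fraction,
            "filvmp_pct_wo_glebs": 100.0 * wo_glebs.filvmp_fraction,
        }
        for name in MOTIF_CLASS_NAMES:
            key = name.replace("/", "").replace("(", "").replace(")", "") \
                      .replace(" ", "_")
            row[f"n_{key}"] = counts.counts[name]
            row[f"density_{key}_per_100aa"] = dens[name]
        try:
            spacers = composition_profile(rec, "spacers", catalog)
            for aa in STANDARD_AA:
                row[f"spacer_{aa}_pct"] = 100.0 * spacers.fractions[aa]
        except SequenceError:
            for aa in STANDARD_AA:
                row[f"spacer_{aa}_pct"] = np.nan
        point = charge_hydropathy_point(rec)
        row["charged_fraction"] = point.charged_fraction
        row["mean_hydrophobicity"] = point.mean_hydrophobicity
        rows.append(row)
    return pd.DataFrame(rows)


def charge_hydropathy_table(
    records: list[FGDomainRecord],
) -> pd.DataFrame:
    pts = [charge_hydropathy_point(r) for r in records]
    return pd.DataFrame({
        "id": [p.id for p in pts],
        "charged_fraction": [p.charged_fraction for p in pts],
        "mean_hydrophobicity": [p.mean_hydrophobicity for p in pts],
    })


def write_table(df: pd.DataFrame, path: str | Path,
                round_decimals: int | None = 1) -> None:
    """Write a TSV ('.' decimal, one header row) plus a JSON mirror."""
    path = Path(path)
    out = df.copy()
    if round_decimals is not None:
        num = out.select_dtypes(include=[np.number]).columns
        out[num] = out[num].round(round_decimals)
    out.to_csv(path, sep="\t", index=False)
    df.to_json(path.with_suffix(".json"), orient="records", indent=2)


def run_profile_report(
    fasta_path: str | Path,
    output_path: str | Path | None = None,
    glebs_map: dict[str, tuple[int, int]] | None = None,
    min_len: int | None = None,
    max_len: int | None = None,
    catalog: MotifCatalog = DEFAULT_CATALOG,
) -> pd.DataFrame:
    """Profile every record of a FASTA file; optionally write TSV+JSON."""
    records = read_fasta(fasta_path, glebs_map=glebs_map)
    if not records:
        raise SequenceError(f"no records in {fasta_path}")
    table = profile_records(records, catalog, min_len=min_len,
                            max_len=max_len)
    if output_path is not None:
        write_table(table, output_path)
    return table


_KNOWN_TOP_KEYS = {"seed", "output_dir", "log_level", "input_fasta", "stages"}
_KNOWN_STAGES = {"sequences", "cloud", "calibration", "titration", "npc",
                 "simulation", "sensitivity"}


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", {})
    unknown = set(stages) - _KNOWN_STAGES
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "input_fasta" in config and \
            not Path(config["input_fasta"]).exists():
        raise FileNotFoundError(config["input_fasta"])
    return config


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _numeric_hash(payload: Any) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "fgphase_run",
    "stages": {
        "sequences": {"enabled": True, "n_domains": 20},
        "cloud": {"enabled": True, "n": 2000, "bins": 50},
        "calibration": {"enabled": True,
                        "true_concentration_molar": 4.7e-3,
                        "labeled_fraction": 1.0 / 714.0,
                        "noise_sd": 0.0, "n_standards": 10},
        "titration": {"enabled": True, "c_crit_molar": 2e-7,
                      "totals_molar": [6e-8, 1e-7, 3e-7, 6.25e-7, 1.25e-6,
                                       2.5e-6, 5e-6, 1e-5],
                      "noise_sd": 0.0},
        "npc": {"enabled": True,
                "species": {"name": "FG domain", "molar_mass_kda": 49.0,
                            "motifs_per_molecule": 39}},
        "simulation": {"enabled": True,
                       "t_points": [10.0, 30.0, 60.0, 120.0, 180.0],
                       "params": {}},
        "sensitivity": {"enabled": False, "params": {}},
    },
}


def _merged_stage(config: dict, name: str) -> dict:
    stage = dict(DEFAULT_CONFIG["stages"][name])
    stage.update(config.get("stages", {}).get(name, {}))
    return stage


def run_full_pipeline(config: dict | None = None) -> dict:
    """Run every enabled stage and write reports to the output directory.

    Stages run in dependency order: synthetic sequences (or an input
    FASTA) -> profile report -> charge/hydropathy cloud and heat map ->
    calibration and titration estimators -> pore-geometry concentrations
    -> influx simulation (and optional sensitivity table).  The returned
    summary (also written as ``summary.json``) records the package
    version, seed, config hash and a hash of the numeric payload, so
    identical configs reproduce identical numbers.
    """
    config = validate_config(dict(config or {}))
    seed = int(config.get("seed", DEFAULT_CONFIG["seed"]))
    outdir = Path(config.get("output_dir", DEFAULT_CONFIG["output_dir"]))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "fgphase_version": __version__,
        "python_version": sys.version.split()[0],
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # --- sequences + profile report -----------------------------------
    stage = _merged_stage(config, "sequences")
    records: list[FGDomainRecord] = []
    if config.get("input_fasta"):
        records = read_fasta(config["input_fasta"])
    elif stage.get("enabled", True):
        kwargs = {k: v for k, v in stage.items() if k != "enabled"}
        cohort = generate_fg_domains(
            SequenceGeneratorSpec(seed=seed, **kwargs))
        records = cohort.records
        write_fasta(records, outdir / "sequences.fasta")
        write_table(cohort.ledger, outdir / "sequence_ledger.tsv",
                    round_decimals=3)
    if records:
        table = profile_records(records)
        write_table(table, outdir / "profile.tsv")
        summary["stages"]["profile"] = {
            "n_records": int(len(table)),
            "median_density_per_100aa": float(
                table["density_all_fg_per_100aa"].median()),
            "median_length": float(table["length"].median()),
        }

    # --- charge/hydropathy cloud --------------------------------------
    stage = _merged_stage(config, "cloud")
    if stage.get("enabled", True):
        n = int(stage.get("n", 2000))
        clouds = {}
        for cohort_name in ("idp_like", "globular_like", "fg_like"):
            pts = generate_cloud(CloudGeneratorSpec(
                cohort=cohort_name, n=n, seed=seed))
            clouds[cohort_name] = pts
        frames = [pd.DataFrame({"cohort": name,
                                "charged_fraction": pts[:, 0],
                                "mean_hydrophobicity": pts[:, 1]})
                  for name, pts in clouds.items()]
        cloud_df = pd.concat(frames, ignore_index=True)
        write_table(cloud_df, outdir / "cloud_points.tsv", round_decimals=4)
        grid = heatmap_bins(clouds["fg_like"], int(stage.get("bins", 50)))
        np.savetxt(outdir / "fg_like_heatmap.tsv", grid, fmt="%d",
                   delimiter="\t")
        summary["stages"]["cloud"] = {
            name: {"mean_charged": float(pts[:, 0].mean()),
                   "mean_hydrophobicity": float(pts[:, 1].mean())}
            for name, pts in clouds.items()
        }

    # --- calibration / titration estimators ---------------------------
    stage = _merged_stage(config, "calibration")
    if stage.get("enabled", True):
        cal = generate_calibration(
            float(stage["true_concentration_molar"]),
            labeled_fraction=float(stage["labeled_fraction"]),
            noise_sd=float(stage.get("noise_sd", 0.0)),
            n_standards=int(stage.get("n_standards", 10)),
            seed=seed,
        )
        summary["stages"]["calibration"] = {
            "true_molar": float(stage["true_concentration_molar"]),
            "estimated_molar": ratiometric_intra_concentration(cal),
        }
    stage = _merged_stage(config, "titration")
    if stage.get("enabled", True):
        tit = generate_titration(
            float(stage["c_crit_molar"]), stage["totals_molar"],
            noise_sd=float(stage.get("noise_sd", 0.0)), seed=seed)
        est = critical_concentration(tit)
        summary["stages"]["titration"] = {
            "true_molar": float(stage["c_crit_molar"]),
            "estimated_molar": est.value_molar,
            "phase_separated": est.phase_separated,
        }

    # --- pore-geometry concentrations ---------------------------------
    stage = _merged_stage(config, "npc")
    if stage.get("enabled", True):
        species = MolecularSpecies(**stage["species"])
        conc = npc_local_concentration(NPCGeometry(), species)
        summary["stages"]["npc"] = {
            "domain_uM": conc["domain_molar"] * 1e6,
            "motifs_mM": conc["motifs_molar"] * 1e3,
            "mass_mg_per_ml": conc["mass_g_per_l"],
        }

    # --- partition-diffusion simulation -------------------------------
    stage = _merged_stage(config, "simulation")
    if stage.get("enabled", True):
        params = TransportParams(**stage.get("params", {}))
        t_points = [float(t) for t in stage["t_points"]]
        sim = simulate(params, t_points)
        long_rows = []
        for it, t in enumerate(sim.times):
            for r, c in zip(sim.grid.centers, sim.profiles[it]):
                long_rows.append({"time_s": t, "radius_um": r,
                                  "concentration": c})
        write_table(pd.DataFrame(long_rows),
                    outdir / "simulation_profile.tsv", round_decimals=None)
        metrics = pd.DataFrame({
            "time_s": sim.times, "mean_intra": sim.mean_intra,
            "mean_extra": sim.mean_extra,
            "intra_extra_ratio": sim.intra_extra_ratio,
            "center_to_rim": sim.center_to_rim, "mass": sim.mass,
        })
        write_table(metrics, outdir / "simulation_metrics.tsv",
                    round_decimals=None)
        i_last = len(t_points) - 1
        summary["stages"]["simulation"] = {
            "final_time_s": float(sim.times[i_last]),
            "mean_intra_final": float(sim.mean_intra[i_last]),
            "intra_extra_ratio_final": float(sim.intra_extra_ratio[i_last]),
            "center_to_rim_final": float(sim.center_to_rim[i_last]),
            "mass_drift_rel": float(
                abs(sim.mass[i_last] / sim.mass[0] - 1.0)),
        }

    stage = _merged_stage(config, "sensitivity")
    if stage.get("enabled", False):
        params = TransportParams(**stage.get("params", {}))
        rows, ranking, influence = sensitivity_analysis(params)
        write_table(pd.DataFrame(rows), outdir / "sensitivity.tsv",
                    round_decimals=None)
        summary["stages"]["sensitivity"] = {
            "ranking": ranking,
            "influence": {k: float(v) for k, v in influence.items()},
        }

    summary["numeric_hash"] = _numeric_hash(summary["stages"])
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
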