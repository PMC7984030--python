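"""Readers, writers, configuration and the end-to-end campaign report.

One tidy-long CSV dialect throughout: UTF-8, '.' decimal, lower-case
headers, '#'-prefixed header comments carrying the seed and config hash so
that outputs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import density as density_mod
from . import quantgen, stats, wab
from .synthetic import (
    CampaignData,
    NoiseModel,
    TrialDesign,
    WeighingSeries,
    default_designs,
    generate_campaign,
)

__all__ = [
    "Campaign",
    "read_weight_csv",
    "read_softening_csv",
    "read_density_csv",
    "read_truth_csv",
    "series_from_frame",
    "write_table",
    "write_campaign",
    "load_config",
    "run_report",
]

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["genotype", "harvest", "rep", "piece", "t_min", "weight_g", "phase"]
_PHASES = {"air", "water"}


@dataclass
class Campaign:
    """Everything needed to run (or re-run) one analysis campaign."""

    out_dir: Path
    seed: int = 0
    config: dict = field(default_factory=dict)
    weights_path: Optional[Path] = None
    softening_path: Optional[Path] = None
    density_path: Optional[Path] = None
    dmc_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    data: Optional[CampaignData] = None


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"{path}: unparseable number {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    return out


def read_weight_csv(path) -> list[WeighingSeries]:
    """Read a tidy weighing table into validated WeighingSeries.

    Required columns: genotype,harvest,rep,piece,t_min,weight_g,phase; an
    optional tare_g column supplies the empty-strainer weight (absent tare
    leaves it None and WAB computation will refuse the record by name).
    Duplicate (genotype,harvest,rep,piece,t_min,phase) rows and unknown
    phases are rejected with the offending row named.
    """
    df = _read_csv(path)
    _require_columns(df, WEIGHT_COLUMNS, path)
    if len(df) == 0:
        return []
    df = df.copy()
    df["t_min"] = _numeric(df, "t_min", path)
    df["weight_g"] = _numeric(df, "weight_g", path)
    if "tare_g" in df.columns:
        df["tare_g"] = _numeric(df, "tare_g", path)
    bad_phase = ~df["phase"].isin(_PHASES)
    if bad_phase.any():
        row = int(np.nonzero(bad_phase.to_numpy())[0][0])
        raise ValueError(
            f"{path}: unknown phase {df['phase'].iloc[row]!r} at data row {row + 1}"
        )
    key_cols = ["genotype", "harvest", "rep", "piece", "t_min", "phase"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0])
        raise ValueError(
            f"{path}: duplicated weighing record at data row {row + 1}: "
            f"{df.loc[df.index[row], key_cols].to_dict()}"
        )
    return series_from_frame(df)


def series_from_frame(df: pd.DataFrame) -> list[WeighingSeries]:
    """Group a tidy weighing frame into per-unit WeighingSeries."""
    out = []
    for (g, h, r, p), sub in df.groupby(
        ["genotype", "harvest", "rep", "piece"], sort=True
    ):
        sub = sub.sort_values("t_min", kind="stable")
        tare = None
        if "tare_g" in sub.columns and sub["tare_g"].notna().any():
            tare = float(sub["tare_g"].dropna().iloc[0])
        out.append(
            WeighingSeries(
                genotype_id=str(g),
                harvest_id=str(h),
                rep_id=str(r),
                unit_id=str(p),
                tare_g=tare,
                t_min=sub["t_min"].to_numpy(dtype=float),
                weight_g=sub["weight_g"].to_numpy(dtype=float),
                phase=sub["phase"].to_numpy(dtype=object),
            )
        )
    return out


def read_softening_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["genotype", "harvest", "rep", "piece", "soft_min",
                          "softened"], path)
    if len(df):
        df = df.copy()
        df["soft_min"] = _numeric(df, "soft_min", path)
        df["softened"] = df["softened"].astype(bool)
    return df


def read_density_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["genotype", "t_min", "weight_in_water_g"], path)
    if len(df):
        df = df.copy()
        df["t_min"] = _numeric(df, "t_min", path)
        df["weight_in_water_g"] = _numeric(df, "weight_in_water_g", path)
    return df


def read_truth_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["genotype", "group", "ct_true"], path)
    return df


def read_dmc_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["genotype", "harvest", "dmc"], path)
    if len(df):
        df = df.copy()
        df["dmc"] = _numeric(df, "dmc", path)
    return df


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: Optional[int] = None,
                cfg_hash: Optional[str] = None) -> None:
    """Write a CSV with reproducibility header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=False)


def write_campaign(data: CampaignData, out_dir, config: Optional[dict] = None) -> dict:
    """Write a simulated campaign as the standard CSV bundle."""
    out_dir = Path(out_dir)
    h = config_hash(config or {})
    paths = {}
    for name, df in [
        ("weights", data.weights),
        ("softening", data.softening),
        ("dmc", data.dmc),
        ("density", data.density),
        ("truth", data.truth),
    ]:
        p = out_dir / f"{name}.csv"
        write_table(df, p, seed=data.seed, cfg_hash=h)
        paths[name] = p
    return paths


def load_config(path) -> dict:
    """Flat key->value YAML config."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def campaign_from_config(config: dict, seed: int) -> CampaignData:
    """Build a campaign from a flat config mapping (every NoiseModel field
    plus n_genotypes may be overridden)."""
    noise_fields = {
        k: config[k]
        for k in ("vg_ct", "ve_ct", "vg_wab", "ve_wab", "convection_range",
                  "scale_resolution", "frag_rate", "den_noise_sd",
                  "dmc_meas_sd")
        if k in config
    }
    noise = NoiseModel(seed=seed, **noise_fields)
    return generate_campaign(
        n_genotypes=int(config.get("n_genotypes", 36)),
        noise=noise,
        seed=seed,
        include_density=bool(config.get("include_density", True)),
    )


# --------------------------------------------------------------------------
# End-to-end report
# --------------------------------------------------------------------------


def _load_campaign(campaign: Campaign) -> CampaignData:
    if campaign.data is not None:
        return campaign.data
    if campaign.weights_path is None or campaign.softening_path is None:
        return campaign_from_config(campaign.config, campaign.seed)
    weights = _read_csv(campaign.weights_path)
    _require_columns(weights, WEIGHT_COLUMNS, campaign.weights_path)
    softening = read_softening_csv(campaign.softening_path)
    dmc = read_dmc_csv(campaign.dmc_path) if campaign.dmc_path else pd.DataFrame(
        columns=["genotype", "harvest", "dmc"]
    )
    density = (
        read_density_csv(campaign.density_path)
        if campaign.density_path
        else pd.DataFrame(columns=["genotype", "harvest", "t_min",
                                   "weight_in_water_g"])
    )
    truth = (
        read_truth_csv(campaign.truth_path)
        if campaign.truth_path
        else pd.DataFrame(columns=["genotype", "group", "ct_true"])
    )
    return CampaignData(weights, softening, dmc, density, truth,
                        seed=campaign.seed)


def run_report(campaign: Campaign) -> dict:
    """Run both pipelines plus the quantitative-genetic layer and write the
    report bundle (CSV tables + run log).  Deterministic under a fixed
    seed: re-running with the same config and seed reproduces every output
    byte for byte."""
    out_dir = Path(campaign.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = config_hash(campaign.config)
    warnings_log: list[str] = []

    data = _load_campaign(campaign)

    # ---- Experiment 1 pipeline
    wab_res = wab.analyze_wab_campaign(
        data.weights, data.softening,
        dmc=data.dmc if len(data.dmc) else None,
    )
    summary = wab_res["summary"].copy()
    n_cens = int(wab_res["ct_table"]["censored"].sum())
    if n_cens:
        warnings_log.append(f"{n_cens} censored replication CT(s) excluded")

    # Fig-4-style letters from per-rep CT spread
    usable = wab_res["ct_table"]
    usable = usable[~usable["censored"]]
    group_counts = usable.groupby("genotype")["ct"].agg(["mean", "var", "count"])
    multi = group_counts[group_counts["count"] > 1]
    if len(multi) >= 2 and (multi["count"] > 1).any():
        df_error = int((multi["count"] - 1).sum())
        mse = float(
            ((multi["count"] - 1) * multi["var"]).sum() / max(df_error, 1)
        )
        if mse > 0 and df_error >= 1:
            la = stats.lsd_bonferroni_letters(
                means=multi["mean"].to_dict(),
                mse=mse,
                df_error=df_error,
                n_per_group=multi["count"].to_dict(),
            )
            summary["letters"] = summary["genotype"].map(la.letters).fillna("")

    # ---- quantgen per harvest (CT and WAB20 traits)
    vc_rows = []
    for harvest, sub in usable.groupby("harvest"):
        t = sub.rename(columns={"ct": "value"})[["genotype", "rep", "value"]]
        try:
            vc = quantgen.variance_components_oneway(
                t, trait="ct", harvest_id=str(harvest)
            )
            vc_rows.append((harvest, "ct", vc.n_reps, vc.vg, vc.ve, vc.h2))
        except ValueError as err:
            warnings_log.append(f"{harvest}/ct: {err}")
    wab20_rows = []
    for c in wab_res["curves"]:
        v = c.at(20.0)
        if np.isfinite(v):
            wab20_rows.append((c.genotype_id, c.harvest_id, c.rep_id, v))
    wab20 = pd.DataFrame(wab20_rows, columns=["genotype", "harvest", "rep", "value"])
    for harvest, sub in wab20.groupby("harvest"):
        try:
            vc = quantgen.variance_components_oneway(
                sub, trait="wab20", harvest_id=str(harvest)
            )
            vc_rows.append((harvest, "wab20", vc.n_reps, vc.vg, vc.ve, vc.h2))
        except ValueError as err:
            warnings_log.append(f"{harvest}/wab20: {err}")
    heritability_table = pd.DataFrame(
        vc_rows, columns=["harvest", "trait", "n_reps", "vg", "ve", "h2"]
    )

    # ---- BLUP of CT (and DMC) across harvests
    blup_tables = {}
    ct_long = usable.rename(columns={"ct": "value"})[
        ["genotype", "harvest", "value"]
    ]
    if ct_long["harvest"].nunique() >= 1 and len(ct_long) > 2:
        try:
            blups = quantgen.blup_across_harvests(ct_long, trait="ct")
            blup_tables["ct"] = pd.DataFrame(
                [(b.genotype_id, b.trait, b.blup_value, b.raw_mean) for b in blups],
                columns=["genotype", "trait", "blup", "raw_mean"],
            )
        except quantgen.ConvergenceError as err:
            warnings_log.append(f"blup/ct: {err}")
    if len(data.dmc):
        dmc_long = data.dmc.rename(columns={"dmc": "value"})
        try:
            blups = quantgen.blup_across_harvests(dmc_long, trait="dmc")
            blup_tables["dmc"] = pd.DataFrame(
                [(b.genotype_id, b.trait, b.blup_value, b.raw_mean) for b in blups],
                columns=["genotype", "trait", "blup", "raw_mean"],
            )
        except quantgen.ConvergenceError as err:
            warnings_log.append(f"blup/dmc: {err}")
    blup_table = (
        pd.concat(blup_tables.values(), ignore_index=True)
        if blup_tables
        else pd.DataFrame(columns=["genotype", "trait", "blup", "raw_mean"])
    )

    # ---- Experiment 2 pipeline
    den_res = None
    if len(data.density):
        cts = dict(zip(summary["genotype"], summary["ct_mean"]))
        den_res = density_mod.analyze_density_campaign(data.density, cts)
        flagged = [c.genotype_id for c in den_res["curves"] if c.flagged]
        if flagged:
            warnings_log.append(
                f"non-monotone/negative density curves flagged: {flagged}"
            )
    else:
        warnings_log.append("no density data: WAB-only report produced")
        logger.info("no density data: WAB-only report produced")

    # ---- truth-recovery diagnostics
    confusion = None
    if len(data.truth) and den_res is not None:
        truth_ct = dict(zip(data.truth["genotype"], data.truth["ct_true"]))
        cls = den_res["classification"]
        rows = []
        for _, row in cls.iterrows():
            g = row["genotype"]
            if g not in truth_ct:
                continue
            actual = "short" if truth_ct[g] <= 30.0 else "long"
            rows.append((g, actual, row["predicted"]))
        cm = pd.DataFrame(rows, columns=["genotype", "actual", "predicted"])
        confusion = (
            cm.groupby(["actual", "predicted"]).size().rename("count").reset_index()
        )

    # ---- write bundle
    tables = {
        "genotype_summary": summary,
        "ct_table": wab_res["ct_table"],
        "correlations": wab_res["correlations"],
        "group_summary": wab_res["group_summary"],
        "heritability": heritability_table,
        "blup": blup_table,
    }
    for harvest, tab in wab_res["subsample"].items():
        tables[f"subsample_{harvest}"] = tab
    if den_res is not None:
        tables["density_features"] = den_res["features"]
        tables["density_r2_grid"] = den_res["regression"]["grid"].reset_index()
        tables["classification"] = den_res["classification"]
    if confusion is not None:
        tables["confusion_matrix"] = confusion

    for name, df in tables.items():
        write_table(df, out_dir / f"{name}.csv", seed=campaign.seed, cfg_hash=h)

    log_lines = [
        f"seed={campaign.seed}",
        f"config_sha256={h}",
        "config=" + json.dumps(campaign.config, sort_keys=True, default=str),
    ] + [f"warning: {w}" for w in warnings_log]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                         encoding="utf-8")
    for w in warnings_log:
        logger.warning(w)

    return {
        "tables": tables,
        "warnings": warnings_log,
        "wab": wab_res,
        "density": den_res,
        "config_hash": h,
    }
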