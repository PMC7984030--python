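"""Experiment 1 analysis: water-absorption curves and cooking time.

The pipeline takes raw strainer weighing records and per-piece softening
observations and produces: per-replication WAB curves on the in-water
clock, cooking times by the k-of-n softening rule (corrected for time the
strainer spent out of the water), CT-group assignments, CT-WAB correlation
tables, the replicate-subsampling design analysis and per-group summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import pearson
from .synthetic import WeighingSeries

__all__ = [
    "WabCurve",
    "CookingRecord",
    "CTResult",
    "GenotypeSummary",
    "compute_wab_curve",
    "determine_cooking_time",
    "group_by_ct",
    "wab_ct_correlation_table",
    "replicate_subsample_analysis",
    "summarize_groups",
    "convection_accuracy_bound",
    "design_ct_table",
    "analyze_wab_campaign",
]

logger = logging.getLogger(__name__)

#: CT at a queried time must match a curve grid point within this (minutes).
_TIME_TOL = 1e-6


@dataclass
class WabCurve:
    """Normalized water-absorption curve for one replication."""

    genotype_id: str
    harvest_id: str
    rep_id: str
    times: np.ndarray  # in-water minutes, strictly increasing from 0
    wab: np.ndarray    # percent of initial net weight

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wab = np.asarray(self.wab, dtype=float)
        if self.times.size == 0 or self.times[0] != 0.0:
            raise ValueError("curve must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.wab)):
            raise ValueError("wab values must be finite")
        if self.wab[0] != 0.0:
            raise ValueError("wab[0] must be 0")

    def at(self, t: float) -> float:
        """WAB at grid time t; NaN if the curve has no such point."""
        idx = np.nonzero(np.abs(self.times - t) < _TIME_TOL)[0]
        return float(self.wab[idx[0]]) if idx.size else float("nan")


@dataclass
class CookingRecord:
    """Softening observations of one replication (total clock)."""

    rep_id: str
    piece_soft_times: np.ndarray          # minutes, NaN = never softened
    out_of_water: list                    # [(start_total_min, duration_min)]
    observation_end: float                # in-water minutes

    def __post_init__(self) -> None:
        self.piece_soft_times = np.asarray(self.piece_soft_times, dtype=float)
        if self.piece_soft_times.size == 0:
            raise ValueError(f"{self.rep_id}: empty piece list")


@dataclass(frozen=True)
class CTResult:
    """Cooking time on the in-water clock, possibly right-censored."""

    ct: float
    censored: bool = False

    @property
    def label(self) -> str:
        return f"> {self.ct:g}" if self.censored else f"{self.ct:g}"


@dataclass
class GenotypeSummary:
    genotype_id: str
    ct_mean: float
    group: str
    wab30_mean: float
    wab30_sd: float
    letters: str = ""


def compute_wab_curve(series: WeighingSeries) -> WabCurve:
    """Water absorption as percent of initial net weight, in-water clock.

    The tare (empty strainer) is subtracted from every gross weight before
    normalisation.  Censored series (legacy protocol stopped at CT) simply
    yield curves ending at CT.
    """
    if series.tare_g is None:
        raise ValueError(
            f"missing tare for {series.genotype_id}/{series.harvest_id}/"
            f"{series.rep_id}: cannot compute net weights"
        )
    times, gross = series.air_events()
    if times.size < 2:
        raise ValueError(
            f"{series.genotype_id}/{series.rep_id}: need a t=0 weighing and "
            "at least one subsequent weighing"
        )
    if abs(times[0]) > _TIME_TOL:
        raise ValueError(f"{series.genotype_id}/{series.rep_id}: no t=0 weighing")
    net = gross - series.tare_g
    net0 = net[0]
    if net0 <= 0:
        raise ValueError(
            f"{series.genotype_id}/{series.rep_id}: non-positive initial net "
            f"weight ({net0:.2f} g)"
        )
    wab = 100.0 * (net - net0) / net0
    wab[0] = 0.0
    times = times.copy()
    times[0] = 0.0
    return WabCurve(series.genotype_id, series.harvest_id, series.rep_id, times, wab)


def determine_cooking_time(record: CookingRecord, required: Optional[int] = None) -> CTResult:
    """CT of a replication by the k-of-n softening rule.

    CT is the k-th order statistic of the piece softening times (k defaults
    to ceil(0.75 n), i.e. 6 of 8) minus the cumulated time the strainer was
    out of the boiling water before that instant.  If fewer than k pieces
    softened within the observation window the replication is censored and
    CT is reported as "> observation end".
    """
    n = record.piece_soft_times.size
    if required is None:
        required = math.ceil(0.75 * n)
    if required > n:
        raise ValueError(f"required={required} exceeds piece count {n}")
    soft = np.sort(record.piece_soft_times[np.isfinite(record.piece_soft_times)])
    if soft.size < required:
        return CTResult(ct=record.observation_end, censored=True)
    t_soft = float(soft[required - 1])
    correction = sum(d for s, d in record.out_of_water if s < t_soft - 1e-12)
    return CTResult(ct=t_soft - correction, censored=False)


def group_by_ct(ct_mean: float) -> str:
    """CT grouping rule: short <= 25 < medium <= 40 < long (minutes)."""
    if not np.isfinite(ct_mean) or ct_mean <= 0:
        raise ValueError(f"ct_mean must be finite and positive, got {ct_mean}")
    if ct_mean <= 25.0:
        return "short"
    if ct_mean <= 40.0:
        return "medium"
    return "long"


def convection_accuracy_bound(convection_range_g: float, gross_weight_g: float) -> float:
    """Worst-case single-weighing WAB distortion (percent of gross weight)
    caused by hot-air convection over the scale."""
    if gross_weight_g <= 0:
        raise ValueError("gross weight must be positive")
    return 100.0 * convection_range_g / gross_weight_g


def wab_ct_correlation_table(
    curves: Iterable[WabCurve],
    cts: dict,
    times: Sequence[float],
) -> pd.DataFrame:
    """Pearson r (and two-sided p) between CT and WAB at each time point.

    ``cts`` maps genotype -> CT minutes (censored genotypes excluded by the
    caller).  Replicate curves are averaged per genotype at each requested
    time before correlating.  Entries with fewer than 3 genotype pairs or
    degenerate variance are reported undefined (NaN), not raised.
    """
    curves = list(curves)
    harvests = sorted({c.harvest_id for c in curves})
    rows = []
    for harvest in harvests:
        hc = [c for c in curves if c.harvest_id == harvest]
        for t in times:
            per_geno: dict[str, list[float]] = {}
            for c in hc:
                v = c.at(t)
                if np.isfinite(v) and c.genotype_id in cts:
                    per_geno.setdefault(c.genotype_id, []).append(v)
            genos = sorted(per_geno)
            x = np.array([cts[g] for g in genos], dtype=float)
            y = np.array([np.mean(per_geno[g]) for g in genos])
            if len(genos) < 3:
                rows.append((harvest, t, np.nan, np.nan, len(genos), False))
                continue
            entry = pearson(x, y, label_x="CT", label_y=f"WAB{t:g}")
            rows.append((harvest, t, entry.r, entry.p, len(genos), entry.significant))
    return pd.DataFrame(
        rows, columns=["harvest", "time", "r", "p", "n", "significant"]
    )


def replicate_subsample_analysis(wab30: pd.DataFrame, cts: dict) -> pd.DataFrame:
    """Correlation between CT and mean WAB30 from every replicate subset.

    ``wab30`` is tidy (genotype, rep, wab30).  For each non-empty subset of
    the replicate labels (Rep1, Rep2, ..., Rep1_2, ..., Rep1_2_3 — indices
    follow the sorted unique rep labels), the subset-mean WAB30 per genotype
    is correlated with CT.  Genotypes missing a rep of the subset are
    dropped from that subset with a logged warning.
    """
    reps = sorted(wab30["rep"].unique())
    if len(reps) < 2:
        raise ValueError("need at least 2 replications")
    pivot = wab30.pivot_table(index="genotype", columns="rep", values="wab30")
    pivot = pivot.loc[[g for g in pivot.index if g in cts]]
    rows = []
    for k in range(1, len(reps) + 1):
        for combo in itertools.combinations(range(len(reps)), k):
            label = "Rep" + "_".join(str(i + 1) for i in combo)
            cols = [reps[i] for i in combo]
            sub = pivot[cols].dropna()
            dropped = len(pivot) - len(sub)
            if dropped:
                logger.warning(
                    "%s: dropped %d genotype(s) with missing replicates",
                    label, dropped,
                )
            if len(sub) < 3:
                rows.append((label, np.nan, np.nan, len(sub)))
                continue
            x = np.array([cts[g] for g in sub.index], dtype=float)
            y = sub.mean(axis=1).to_numpy()
            entry = pearson(x, y, label_x="CT", label_y=label)
            rows.append((label, entry.r, entry.p, len(sub)))
    return pd.DataFrame(rows, columns=["subset", "r", "p", "n"])


def summarize_groups(
    summaries: pd.DataFrame, den30: Optional[dict] = None
) -> pd.DataFrame:
    """Per-group mean +/- sample SD of WAB30 (and of weight-in-water percent
    at 30 min when provided).

    ``summaries`` needs columns genotype, group, wab30.  Empty groups give
    undefined (NaN) entries; singleton groups give an undefined SD.
    """
    rows = []
    for group in ("short", "medium", "long"):
        sub = summaries[summaries["group"] == group]
        vals = sub["wab30"].dropna().to_numpy(dtype=float)
        mean = float(np.mean(vals)) if vals.size else np.nan
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        row = {"group": group, "n": vals.size, "wab30_mean": mean, "wab30_sd": sd}
        if den30 is not None:
            dv = np.array(
                [den30[g] for g in sub["genotype"] if g in den30], dtype=float
            )
            row["den30_mean"] = float(np.mean(dv)) if dv.size else np.nan
            row["den30_sd"] = float(np.std(dv, ddof=1)) if dv.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def design_ct_table(profiles, design, noise, rng) -> pd.DataFrame:
    """Per-replication cooking times for a set of genotypes under one trial
    design — tidy (genotype, rep, value) rows ready for variance-component
    estimation.  Censored replications are dropped."""
    from .synthetic import simulate_wab_trial

    rows = []
    for prof in profiles:
        for res in simulate_wab_trial(prof, design, noise, rng=rng):
            record = CookingRecord(
                rep_id=res.series.rep_id,
                piece_soft_times=res.piece_soft_times,
                out_of_water=res.series.out_of_water_intervals(),
                observation_end=res.observation_end,
            )
            ct = determine_cooking_time(record)
            if not ct.censored:
                rows.append((prof.genotype_id, res.series.rep_id, ct.ct))
    return pd.DataFrame(rows, columns=["genotype", "rep", "value"])


# --------------------------------------------------------------------------
# Campaign-level pipeline
# --------------------------------------------------------------------------


def _records_from_frames(weights: pd.DataFrame, softening: pd.DataFrame):
    """Yield (series, cooking_record) per (genotype, harvest, rep)."""
    from .io import series_from_frame  # local import, io depends on wab

    series_list = series_from_frame(weights)
    soft_idx = softening.groupby(["genotype", "harvest", "rep"])
    for s in series_list:
        key = (s.genotype_id, s.harvest_id, s.rep_id)
        try:
            sub = soft_idx.get_group(key)
        except KeyError:
            continue
        times = sub["soft_min"].to_numpy(dtype=float)
        softened = sub["softened"].astype(bool).to_numpy()
        times = np.where(softened, times, np.nan)
        iw_end = s.t_min[-1] - sum(d for _, d in s.out_of_water_intervals())
        record = CookingRecord(
            rep_id=s.rep_id,
            piece_soft_times=times,
            out_of_water=s.out_of_water_intervals(),
            observation_end=float(max(iw_end, 0.0)),
        )
        yield s, record


def analyze_wab_campaign(
    weights: pd.DataFrame,
    softening: pd.DataFrame,
    dmc: Optional[pd.DataFrame] = None,
    times: Sequence[float] = (10.0, 20.0, 30.0),
    censored_policy: str = "exclude",
    max_boil: float = 60.0,
) -> dict:
    """Run the full Experiment-1 pipeline on tidy campaign tables.

    Returns a dict with per-rep CT table, per-genotype summary (CT mean,
    group, WAB30), correlation tables (CT vs WAB at ``times`` per harvest,
    CT vs DMC if provided), the replicate-subsample analysis for multi-piece
    harvests, and all computed WAB curves.

    ``censored_policy``: 'exclude' drops censored replication CTs from means
    and correlations (default); 'max_boil' substitutes the observation end.
    """
    if censored_policy not in ("exclude", "max_boil"):
        raise ValueError("censored_policy must be 'exclude' or 'max_boil'")

    curves, ct_rows = [], []
    n_censored = 0
    for series, record in _records_from_frames(weights, softening):
        curves.append(compute_wab_curve(series))
        res = determine_cooking_time(record)
        if res.censored:
            n_censored += 1
        ct_rows.append(
            (series.genotype_id, series.harvest_id, series.rep_id,
             res.ct, res.censored, res.label)
        )
    if n_censored:
        logger.warning("%d censored replication CT(s)", n_censored)
    ct_table = pd.DataFrame(
        ct_rows, columns=["genotype", "harvest", "rep", "ct", "censored", "label"]
    )

    usable = ct_table.copy()
    if censored_policy == "exclude":
        usable = usable[~usable["censored"]]
    else:
        usable.loc[usable["censored"], "ct"] = max_boil

    ct_mean = usable.groupby("genotype")["ct"].mean()

    # WAB30 per rep, from harvests whose curves reach 30 min
    wab30_rows = []
    for c in curves:
        v = c.at(30.0)
        if np.isfinite(v):
            wab30_rows.append((c.genotype_id, c.harvest_id, c.rep_id, v))
    wab30 = pd.DataFrame(wab30_rows, columns=["genotype", "harvest", "rep", "wab30"])

    summary_rows = []
    for g, ctm in ct_mean.items():
        sub = wab30[wab30["genotype"] == g]["wab30"]
        summary_rows.append(
            {
                "genotype": g,
                "ct_mean": float(ctm),
                "group": group_by_ct(float(ctm)),
                "wab30": float(sub.mean()) if len(sub) else np.nan,
                "wab30_sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows)

    cts = dict(zip(summary["genotype"], summary["ct_mean"]))
    corr = wab_ct_correlation_table(curves, cts, times)

    corr_dmc = None
    if dmc is not None and len(dmc):
        dmc_mean = dmc.groupby("genotype")["dmc"].mean()
        common = sorted(set(dmc_mean.index) & set(cts))
        if len(common) >= 3:
            entry = pearson(
                np.array([cts[g] for g in common]),
                dmc_mean.loc[common].to_numpy(),
                label_x="CT", label_y="DMC",
            )
            corr_dmc = entry
            summary = summary.merge(
                dmc_mean.rename("dmc").reset_index(), on="genotype", how="left"
            )

    # replicate-subsampling only on harvests whose WAB30 coverage is nearly
    # complete (the optimised protocol); legacy harvests that stopped
    # weighing at CT would drop most genotypes from every subset
    subsample = {}
    n_geno = len(summary)
    for harvest, sub in wab30.groupby("harvest"):
        n_reps = sub["rep"].nunique()
        coverage = len(sub) / max(n_geno * n_reps, 1)
        if n_reps >= 2 and coverage >= 0.9:
            subsample[harvest] = replicate_subsample_analysis(sub, cts)

    return {
        "curves": curves,
        "ct_table": ct_table,
        "wab30": wab30,
        "summary": summary,
        "correlations": corr,
        "ct_dmc": corr_dmc,
        "subsample": subsample,
        "group_summary": summarize_groups(summary),
    }
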