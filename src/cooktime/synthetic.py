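"""Synthetic boiling-trial generator.

Emulates the measurement structure of two cassava cooking-time protocols:

* Experiment 1 — strainers of root pieces are boiled, lifted out roughly
  once every ten in-water minutes, towel-dried, weighed in air on a 0.01 g
  scale and returned to the pot.  Weight gain as percent of initial weight
  is water absorption (WAB); the time at which a stated fraction of pieces
  turn soft (corrected for time spent out of the water) is cooking time (CT).
* Experiment 2 — a mesh bag of root pieces hangs from a scale while fully
  immersed in boiling water; the apparent (hydrostatic) weight is logged
  every five minutes and tracks the fall in relative density as starch
  gelatinises and the tissue swells.

The generator's latent truth is a :class:`GenotypeProfile` per genotype.
Cooking-time groups (short / medium / long), their proportions, the
WAB-at-30-min group means and spreads, the harvest-level shifts, the hot-air
convection weighing noise and the two protocol variants (1 piece x many reps
vs 8 pieces x 3 reps) all follow the magnitudes of the field study this
package is designed around.  Everything is deterministic under a fixed seed.

Units: grams, minutes, percent throughout.  All analysis time axes are
cumulative *in-water* minutes; intervals spent out of the water for weighing
are excluded from the boiling clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeProfile",
    "TrialDesign",
    "NoiseModel",
    "WeighingSeries",
    "WabTrialResult",
    "CampaignData",
    "SimulationError",
    "GROUP_CT_RANGES",
    "GROUP_WAB30_SD",
    "WAB30_TREND",
    "generate_genotypes",
    "simulate_wab_trial",
    "simulate_density_trial",
    "simulate_trait_table",
    "generate_campaign",
    "default_designs",
    "density_design",
    "hydrostatic_weight",
    "dmc_to_relative_density",
]


class SimulationError(RuntimeError):
    """Raised when a simulated physical configuration is impossible."""


# --------------------------------------------------------------------------
# Latent truth
# --------------------------------------------------------------------------

#: CT intervals (minutes) defining the three cooking groups.  The long group
#: is capped at a configurable maximum boiling time (default 60 min).
GROUP_CT_RANGES = {"short": (15.0, 25.0), "medium": (25.0, 40.0), "long": (40.0, 60.0)}

#: Genotype-level spread of true WAB at 30 min within each CT group (percent).
GROUP_WAB30_SD = {"short": 3.1, "medium": 1.7, "long": 3.8}

#: Anchor points (CT minutes -> WAB30 percent) for the mean WAB30 trend:
#: group-centre CTs mapped to the observed group mean water absorption.
WAB30_TREND = ((20.0, 15.3), (32.5, 10.7), (50.0, 4.9))

#: Group spread of the normalized weight-in-water value at 30 min (percent
#: of initial DEN).  The hydrostatic experiment uses its own root samples,
#: so its genotype deviations are calibrated to these observed spreads
#: rather than inheriting the full WAB30 scatter.
GROUP_DEN30_SD = {"short": 9.8, "medium": 11.1, "long": 6.9}

#: Mean and SD of the volume-swelling ratio: cm^3 of volume gained per gram
#: of absorbed water.  Calibrated so the density-loss slope of a genotype at
#: the CT = 30 min boundary sits at the -1.25 %/min screening threshold.
SWELL_ALPHA_MEAN = 1.41
SWELL_ALPHA_SD = 0.02

#: Fragmentation starts this many minutes after the genotype's true CT for
#: fast cookers; pieces crumble through the strainer/bag mesh.
FRAG_DELAY_MIN = 10.0

#: Specific-gravity map from dry matter content, classical linear regression
#: family for root crops: d0 = (DMC + 142) / 158.3 (generator constant).
_DENSITY_INTERCEPT = 142.0
_DENSITY_SLOPE = 158.3


def dmc_to_relative_density(dmc: float) -> float:
    """Map dry matter content (percent) to initial relative density d0 > 1."""
    return (dmc + _DENSITY_INTERCEPT) / _DENSITY_SLOPE


@dataclass(frozen=True)
class GenotypeProfile:
    """Latent truth for one genotype.

    frag_onset is the in-water time (minutes) at which root pieces start to
    fragment and lose mass into the water — an artefact shown only by very
    fast cookers — or None for genotypes that stay intact.
    """

    genotype_id: str
    group: str
    ct_true: float          # minutes
    wab_max: float          # percent of initial fresh weight, saturation level
    wab_tau: float          # minutes, uptake time constant
    dmc_true: float         # percent dry weight / fresh weight
    swell_alpha: float      # volume gained per gram absorbed / water volume
    frag_onset: Optional[float] = None
    wab30_dev: float = 0.0  # genotype WAB30 deviation from the CT trend, %

    def __post_init__(self) -> None:
        if self.ct_true <= 0:
            raise ValueError(f"{self.genotype_id}: ct_true must be positive")
        if self.group not in GROUP_CT_RANGES:
            raise ValueError(f"{self.genotype_id}: unknown group {self.group!r}")
        lo, hi = GROUP_CT_RANGES[self.group]
        # group label must be consistent with the CT grouping rule
        if self.group == "short" and self.ct_true > 25.0:
            raise ValueError(f"{self.genotype_id}: short group requires ct <= 25")
        if self.group == "medium" and not (25.0 < self.ct_true <= 40.0):
            raise ValueError(f"{self.genotype_id}: medium group requires 25 < ct <= 40")
        if self.group == "long" and self.ct_true <= 40.0:
            raise ValueError(f"{self.genotype_id}: long group requires ct > 40")
        if not (0.0 <= self.wab_max <= 40.0):
            raise ValueError(f"{self.genotype_id}: wab_max outside [0, 40]")
        if self.wab_tau <= 0:
            raise ValueError(f"{self.genotype_id}: wab_tau must be positive")
        if not (20.0 < self.dmc_true < 50.0):
            raise ValueError(f"{self.genotype_id}: dmc_true outside (20, 50)")
        if self.swell_alpha < 1.0:
            raise ValueError(f"{self.genotype_id}: swell_alpha must be >= 1")

    def wab(self, t, frag_rate: float = 0.0):
        """True water absorption (percent of initial weight) at in-water time t.

        Saturating uptake wab_max * (1 - exp(-t / tau)); after ``frag_onset``
        a linear mass-loss term at ``frag_rate`` %/min makes the recorded
        curve non-monotone (fragment loss masquerades as weight loss).
        """
        t = np.asarray(t, dtype=float)
        w = self.wab_max * (1.0 - np.exp(-t / self.wab_tau))
        if self.frag_onset is not None and frag_rate > 0:
            w = w - frag_rate * np.clip(t - self.frag_onset, 0.0, None)
        return w if w.ndim else float(w)


@dataclass(frozen=True)
class TrialDesign:
    """One harvest's boiling-trial layout."""

    harvest_id: str
    map_age: int                    # months after planting
    n_reps: int
    pieces_per_rep: int
    weigh_interval: float = 10.0    # minutes (10 for WAB, 5 for density)
    max_boil: float = 60.0          # minutes
    stop_at_ct: bool = False        # legacy behaviour: stop weighing at CT
    harvest_ct_shift: float = 0.0   # minutes added to every CT this harvest
    harvest_dmc_shift: float = 0.0  # percent added to every DMC this harvest

    def __post_init__(self) -> None:
        if self.n_reps < 1 or self.pieces_per_rep < 1:
            raise ValueError("n_reps and pieces_per_rep must be >= 1")
        if self.weigh_interval <= 0:
            raise ValueError("weigh_interval must be positive")
        if self.max_boil > 60.0:
            raise ValueError("max_boil must be <= 60 min")


@dataclass(frozen=True)
class NoiseModel:
    """Variance structure and measurement noise of the campaign.

    vg_* / ve_* are genotype and residual variance magnitudes (min^2 or %^2)
    used by the direct trait simulator and for per-piece softening spread.
    convection_range is the full width (grams) of the uniform perturbation of
    an in-air weighing caused by hot-air convection over the scale pan;
    scale_resolution is the scale's display resolution.
    """

    vg_ct: float = 150.0
    ve_ct: float = 12.0
    vg_wab: float = 20.0
    ve_wab: float = 5.0
    convection_range: float = 20.0
    scale_resolution: float = 0.01
    frag_rate: float = 0.4          # percent of initial weight lost per min
    den_noise_sd: float = 0.5       # grams, hanging-scale jitter in water
    dmc_meas_sd: float = 0.5        # percent, oven-drying duplicate error
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vg_ct", "ve_ct", "vg_wab", "ve_wab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.convection_range < 0:
            raise ValueError("convection_range must be >= 0")
        if self.scale_resolution <= 0:
            raise ValueError("scale_resolution must be positive")


# --------------------------------------------------------------------------
# Weighing records
# --------------------------------------------------------------------------


@dataclass
class WeighingSeries:
    """Timestamped gross weights of one strainer or bag.

    t_min is the *total* clock (boiling start = 0).  ``phase`` is 'air' for a
    weighing event (unit out of the water, weight recorded) and 'water' for a
    return-to-water event.  The in-water clock is reconstructed by removing
    completed air intervals.  ``tare_g`` is the empty strainer/bag weight;
    None means the tare was never recorded (an error downstream).
    """

    genotype_id: str
    harvest_id: str
    rep_id: str
    unit_id: str
    tare_g: Optional[float]
    t_min: np.ndarray
    weight_g: np.ndarray
    phase: np.ndarray  # array of 'air' / 'water'

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.weight_g = np.asarray(self.weight_g, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.t_min) == len(self.weight_g) == len(self.phase)):
            raise ValueError("t_min, weight_g and phase must have equal length")
        if np.any(np.diff(self.t_min) < 0):
            raise ValueError("events must be in chronological order")

    def air_events(self):
        """(in_water_time, recorded_weight) for every in-air weighing."""
        times, weights = [], []
        accrued = 0.0
        out_since = None
        for t, w, ph in zip(self.t_min, self.weight_g, self.phase):
            if ph == "air":
                times.append(t - accrued)
                weights.append(w)
                out_since = t
            elif ph == "water":
                if out_since is not None:
                    accrued += t - out_since
                    out_since = None
            else:
                raise ValueError(f"unknown phase {ph!r}")
        return np.asarray(times), np.asarray(weights)

    def out_of_water_intervals(self):
        """Completed (start_total_min, duration_min) air intervals."""
        intervals = []
        out_since = None
        for t, ph in zip(self.t_min, self.phase):
            if ph == "air":
                out_since = t
            elif ph == "water" and out_since is not None:
                if t > out_since:
                    intervals.append((out_since, t - out_since))
                out_since = None
        return intervals


@dataclass
class WabTrialResult:
    """One replication of the WAB/CT protocol."""

    series: WeighingSeries
    piece_soft_times: np.ndarray   # total clock, minutes; NaN if never soft
    softened: np.ndarray           # bool per piece
    observation_end: float         # in-water minutes


# --------------------------------------------------------------------------
# Genotype generation
# --------------------------------------------------------------------------


def _quota_counts(n: int, props: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n among len(props) groups."""
    raw = [n * p for p in props]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_genotypes(
    n: int,
    group_props: Sequence[float] = (15 / 34, 8 / 34, 11 / 34),
    config: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    ct_max: float = 60.0,
) -> list[GenotypeProfile]:
    """Draw ``n`` genotype truth profiles.

    Group sizes are fixed by deterministic largest-remainder quotas on
    ``group_props`` (default 15:8:11, the observed short/medium/long group
    counts); true CT is uniform within the group's CT interval (long capped at
    ``ct_max``); WAB30 truth follows the piecewise-linear CT trend with
    group-specific scatter; uptake time constants rise with CT so that fast
    cookers absorb water faster.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    props = list(group_props)
    if len(props) != 3 or any(p < 0 for p in props):
        raise ValueError("group_props must be 3 non-negative values")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("group_props must sum to 1")
    config = config or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    counts = _quota_counts(n, props)
    groups = [g for g, c in zip(("short", "medium", "long"), counts) for _ in range(c)]

    xs = [a[0] for a in WAB30_TREND]
    ys = [a[1] for a in WAB30_TREND]

    profiles = []
    for i, group in enumerate(groups):
        lo, hi = GROUP_CT_RANGES[group]
        hi = min(hi, ct_max) if group == "long" else hi
        ct = float(rng.uniform(lo, hi))
        trend = float(np.interp(ct, xs, ys))
        wab30 = float(np.clip(
            trend + rng.normal(0.0, GROUP_WAB30_SD[group]), 0.5, 38.0
        ))
        tau = 0.5 * ct
        wab_max = float(np.clip(wab30 / (1.0 - math.exp(-30.0 / tau)), 0.0, 40.0))
        dmc = float(np.clip(rng.normal(38.0, 3.5), 20.5, 49.5))
        alpha = float(max(1.0, rng.normal(SWELL_ALPHA_MEAN, SWELL_ALPHA_SD)))
        frag = ct + FRAG_DELAY_MIN if group == "short" else None
        profiles.append(
            GenotypeProfile(
                genotype_id=f"G{i + 1:03d}",
                group=group,
                ct_true=ct,
                wab_max=wab_max,
                wab_tau=tau,
                dmc_true=dmc,
                swell_alpha=alpha,
                frag_onset=frag,
                wab30_dev=wab30 - trend,
            )
        )
    return profiles


# --------------------------------------------------------------------------
# Experiment 1 simulation
# --------------------------------------------------------------------------

_PIECE_WEIGHT_RANGE = (55.0, 70.0)   # grams per half-cylinder piece
_TARE_RANGE = (250.0, 350.0)         # grams, strainer (multi-piece reps)
_TRAY_TARE_RANGE = (25.0, 35.0)      # grams, light tray for single pieces
_OUT_MEAN_S = 60.0                   # seconds out of water per weighing
_OUT_HALF_WIDTH_S = 10.0             # +/- seconds, uniform

#: Gross weight (g) at which the full convection_range applies; the hot-air
#: disturbance scales with the weighed assembly's drag area, proxied by its
#: gross weight (a lone piece on a tray barely moves the display).
_CONVECTION_REF_GROSS = 1000.0


def _round_to(x, resolution: float):
    return np.round(np.asarray(x, dtype=float) / resolution) * resolution


def simulate_wab_trial(
    profile: GenotypeProfile,
    design: TrialDesign,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
) -> list[WabTrialResult]:
    """Simulate all replications of the WAB/CT protocol for one genotype.

    Per replication: pieces are loaded into a tared strainer, softening times
    are drawn around the genotype's true CT (plus the harvest shift) with
    per-piece variance ``ve_ct``, and the strainer is weighed on the in-water
    grid (every ``weigh_interval`` min).  Each weighing perturbs the gross
    weight by uniform convection noise and appends a ~1 min out-of-water
    interval to the record.  With ``stop_at_ct`` the weighing series
    truncates at the replication's CT (legacy protocol), otherwise it runs
    to ``max_boil``.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    k_required = math.ceil(0.75 * design.pieces_per_rep)
    results = []
    for rep in range(1, design.n_reps + 1):
        n_pieces = design.pieces_per_rep
        piece_w = rng.uniform(*_PIECE_WEIGHT_RANGE, size=n_pieces)
        net0 = float(piece_w.sum())
        tare_range = _TARE_RANGE if n_pieces > 1 else _TRAY_TARE_RANGE
        tare = float(rng.uniform(*tare_range))

        # rep-level kinetic deviation pools over pieces
        wab_dev = float(rng.normal(0.0, math.sqrt(noise.ve_wab / n_pieces)))
        eff = replace(
            profile,
            wab_max=float(np.clip(profile.wab_max + wab_dev, 0.0, 40.0)),
        )

        soft_iw = profile.ct_true + design.harvest_ct_shift + rng.normal(
            0.0, math.sqrt(noise.ve_ct), size=n_pieces
        )
        soft_iw = np.clip(soft_iw, 1.0, None)
        softened = soft_iw <= design.max_boil
        order = np.sort(soft_iw[softened])
        if order.size >= k_required:
            ct_rep_iw = float(order[k_required - 1])
        else:
            ct_rep_iw = float(design.max_boil)  # censored replication

        # weighing schedule on the in-water clock
        grid = np.arange(
            design.weigh_interval, design.max_boil + 1e-9, design.weigh_interval
        )
        if design.stop_at_ct:
            sched = list(grid[grid < ct_rep_iw - 1e-9]) + [ct_rep_iw]
        else:
            sched = list(grid)

        events_t, events_w, events_ph = [0.0, 0.0], [None, None], ["air", "water"]
        w0 = float(_round_to(tare + net0, noise.scale_resolution))
        events_w[0] = events_w[1] = w0

        accrued = 0.0
        air_starts_iw = []  # in-water times at which air intervals occurred
        air_durs = []
        for t_iw in sched:
            true_net = net0 * (1.0 + eff.wab(t_iw, noise.frag_rate) / 100.0)
            gross = tare + true_net
            if noise.convection_range > 0:
                half = (noise.convection_range / 2.0) * (
                    gross / _CONVECTION_REF_GROSS
                )
                gross += rng.uniform(-half, half)
            gross = float(_round_to(gross, noise.scale_resolution))
            dur = (_OUT_MEAN_S + rng.uniform(-_OUT_HALF_WIDTH_S, _OUT_HALF_WIDTH_S)) / 60.0
            t_out = t_iw + accrued
            events_t += [t_out, t_out + dur]
            events_w += [gross, gross]
            events_ph += ["air", "water"]
            air_starts_iw.append(t_iw)
            air_durs.append(dur)
            accrued += dur

        # piece softening on the total clock: add air time accrued before
        # the piece's in-water softening instant
        starts = np.asarray(air_starts_iw)
        durs = np.asarray(air_durs)
        soft_total = np.where(
            softened,
            soft_iw + np.array(
                [durs[starts < s - 1e-12].sum() for s in soft_iw]
            ),
            np.nan,
        )

        series = WeighingSeries(
            genotype_id=profile.genotype_id,
            harvest_id=design.harvest_id,
            rep_id=f"R{rep}",
            unit_id="strainer",
            tare_g=tare,
            t_min=np.asarray(events_t),
            weight_g=np.asarray(events_w),
            phase=np.asarray(events_ph, dtype=object),
        )
        results.append(
            WabTrialResult(
                series=series,
                piece_soft_times=soft_total,
                softened=softened,
                observation_end=float(design.max_boil),
            )
        )
    return results


# --------------------------------------------------------------------------
# Experiment 2 simulation
# --------------------------------------------------------------------------

_BAG_WEIGHT_RANGE = (1000.0, 1100.0)  # grams in air
_BAG_PIECES = 16                      # 12-20 longitudinal quarters pooled

#: Reference DMC for the den30-per-wab30 sensitivity used to rescale
#: genotype deviations to the observed DEN30 group spreads.
_REF_DMC = 38.5


def _den30_per_wab30() -> float:
    """Percent of initial DEN lost at 30 min per percent of WAB30, at the
    reference density and default swell ratio."""
    d0 = dmc_to_relative_density(_REF_DMC)
    return (SWELL_ALPHA_MEAN - 1.0) * d0 / (d0 - 1.0)


def hydrostatic_weight(m0: float, d0: float, absorbed_g, swell_alpha: float):
    """Apparent weight (g) of a submerged sample after absorbing water.

    m0 grams of tissue with initial relative density d0 (> 1) absorb
    ``absorbed_g`` grams of water; each absorbed gram adds ``swell_alpha``
    times its own volume to the sample.  With water density 1 g/cm^3:

        weight_in_water = (m0 + a) - (m0/d0 + swell_alpha * a)
    """
    a = np.asarray(absorbed_g, dtype=float)
    w = (m0 + a) - (m0 / d0 + swell_alpha * a)
    return w if w.ndim else float(w)


def density_design(harvest_id: str = "H-10M") -> TrialDesign:
    """Default hydrostatic-weighing layout: one bag, 5-min grid, 60 min."""
    return TrialDesign(
        harvest_id=harvest_id,
        map_age=10,
        n_reps=1,
        pieces_per_rep=_BAG_PIECES,
        weigh_interval=5.0,
        max_boil=60.0,
        stop_at_ct=False,
    )


def simulate_density_trial(
    profile: GenotypeProfile,
    design: TrialDesign,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
) -> WeighingSeries:
    """Simulate the immersed-weight series of one bag of root pieces.

    The bag never leaves the water; every ``weigh_interval`` minutes the
    hanging scale records m(t) - rho * V(t).  Swelling (swell_alpha >= 1)
    makes the apparent weight fall as water is absorbed; fragmentation of
    fast cookers reverses the trend near the end of boiling.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    m0 = float(rng.uniform(*_BAG_WEIGHT_RANGE))
    dmc = profile.dmc_true + design.harvest_dmc_shift
    d0 = dmc_to_relative_density(dmc)
    if d0 <= 1.0:
        raise SimulationError(
            f"{profile.genotype_id}: initial relative density {d0:.3f} <= 1, "
            "the sample would float and cannot be weighed hydrostatically"
        )
    # The hydrostatic trial uses its own root samples: the genotype's WAB30
    # deviation from the CT trend is rescaled so that the resulting DEN30
    # spread per CT group matches the observed group SDs, while remaining
    # fully associated with the uptake deviation of the WAB experiment.
    sat = 1.0 - math.exp(-30.0 / profile.wab_tau)
    trend30 = profile.wab_max * sat - profile.wab30_dev
    scale = GROUP_DEN30_SD[profile.group] / (
        _den30_per_wab30() * GROUP_WAB30_SD[profile.group]
    )
    bag_dev = float(rng.normal(0.0, math.sqrt(noise.ve_wab / design.pieces_per_rep)))
    den_wab30 = trend30 + scale * profile.wab30_dev + bag_dev
    eff = replace(
        profile,
        wab_max=float(np.clip(den_wab30 / sat, 0.0, 40.0)),
        wab30_dev=0.0,
    )

    times = np.arange(0.0, design.max_boil + 1e-9, design.weigh_interval)
    absorbed = m0 * eff.wab(times, noise.frag_rate) / 100.0
    w = hydrostatic_weight(m0, d0, absorbed, profile.swell_alpha)
    jitter = np.zeros_like(w)
    if noise.den_noise_sd > 0:
        jitter = rng.normal(0.0, noise.den_noise_sd, size=w.shape)
        jitter[0] = 0.0  # the time-0 reference weighing is taken with care
    w = _round_to(w + jitter, noise.scale_resolution)

    return WeighingSeries(
        genotype_id=profile.genotype_id,
        harvest_id=design.harvest_id,
        rep_id="R1",
        unit_id="bag",
        tare_g=0.0,
        t_min=times,
        weight_g=w,
        phase=np.asarray(["water"] * len(times), dtype=object),
    )


# --------------------------------------------------------------------------
# Direct trait simulator (variance-component recovery studies)
# --------------------------------------------------------------------------


def simulate_trait_table(
    n_genotypes: int,
    n_reps: int,
    vg: float,
    ve: float,
    rng: Optional[np.random.Generator] = None,
    mu: float = 30.0,
) -> pd.DataFrame:
    """Balanced one-way genotype trial: value = mu + g_i + e_ij.

    g_i ~ N(0, vg), e_ij ~ N(0, ve).  Tidy frame with columns
    genotype, rep, value — the input dialect of the variance-component
    estimator.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    g = rng.normal(0.0, math.sqrt(vg), size=n_genotypes)
    e = rng.normal(0.0, math.sqrt(ve), size=(n_genotypes, n_reps))
    values = mu + g[:, None] + e
    return pd.DataFrame(
        {
            "genotype": np.repeat([f"G{i + 1:03d}" for i in range(n_genotypes)], n_reps),
            "rep": np.tile([f"R{j + 1}" for j in range(n_reps)], n_genotypes),
            "value": values.ravel(),
        }
    )


# --------------------------------------------------------------------------
# Campaign generation
# --------------------------------------------------------------------------


def default_designs() -> list[TrialDesign]:
    """The four monthly harvests with their protocol variants.

    The first two harvests use the legacy single-piece protocol and stop
    weighing at CT; the last two use the optimised 8-piece x 3-rep protocol
    and keep weighing to 60 min.  Harvest shifts reproduce the observed
    pattern: fastest cooking at 9-10 months, rising dry matter with age.
    """
    return [
        TrialDesign("H-8M", 8, 4, 1, stop_at_ct=True,
                    harvest_ct_shift=3.0, harvest_dmc_shift=-1.5),
        TrialDesign("H-9M", 9, 6, 1, stop_at_ct=True,
                    harvest_ct_shift=-3.0, harvest_dmc_shift=-2.5),
        TrialDesign("H-10M", 10, 3, 8, stop_at_ct=False,
                    harvest_ct_shift=-1.0, harvest_dmc_shift=0.5),
        TrialDesign("H-11M", 11, 3, 8, stop_at_ct=False,
                    harvest_ct_shift=2.0, harvest_dmc_shift=1.0),
    ]


@dataclass
class CampaignData:
    """Tidy tables of one simulated campaign."""

    weights: pd.DataFrame    # genotype,harvest,rep,piece,t_min,weight_g,phase,tare_g
    softening: pd.DataFrame  # genotype,harvest,rep,piece,soft_min,softened
    dmc: pd.DataFrame        # genotype,harvest,dmc
    density: pd.DataFrame    # genotype,harvest,t_min,weight_in_water_g
    truth: pd.DataFrame      # genotype,group,ct_true,dmc_true,...
    seed: int = 0


def generate_campaign(
    n_genotypes: int = 36,
    designs: Optional[list[TrialDesign]] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    include_density: bool = True,
    density_harvest: str = "H-10M",
) -> CampaignData:
    """Simulate a full multi-harvest campaign as tidy long tables."""
    noise = noise or NoiseModel(seed=seed)
    designs = designs if designs is not None else default_designs()
    root = np.random.default_rng(seed)
    profiles = generate_genotypes(n_genotypes, config=noise, rng=root)

    w_rows, s_rows, dmc_rows, den_rows = [], [], [], []
    for design in designs:
        for prof in profiles:
            reps = simulate_wab_trial(prof, design, noise, rng=root)
            for res in reps:
                s = res.series
                for t, w, ph in zip(s.t_min, s.weight_g, s.phase):
                    w_rows.append(
                        (s.genotype_id, s.harvest_id, s.rep_id, s.unit_id,
                         t, w, ph, s.tare_g)
                    )
                for p, (st, ok) in enumerate(
                    zip(res.piece_soft_times, res.softened), start=1
                ):
                    s_rows.append(
                        (s.genotype_id, s.harvest_id, s.rep_id, f"P{p}",
                         st if ok else np.nan, bool(ok))
                    )
            dmc_meas = (
                prof.dmc_true + design.harvest_dmc_shift
                + root.normal(0.0, noise.dmc_meas_sd)
            )
            dmc_rows.append((prof.genotype_id, design.harvest_id, dmc_meas))

    if include_density:
        dd = density_design(density_harvest)
        for prof in profiles:
            s = simulate_density_trial(prof, dd, noise, rng=root)
            for t, w in zip(s.t_min, s.weight_g):
                den_rows.append((s.genotype_id, s.harvest_id, t, w))

    weights = pd.DataFrame(
        w_rows,
        columns=["genotype", "harvest", "rep", "piece", "t_min", "weight_g",
                 "phase", "tare_g"],
    )
    softening = pd.DataFrame(
        s_rows,
        columns=["genotype", "harvest", "rep", "piece", "soft_min", "softened"],
    )
    dmc = pd.DataFrame(dmc_rows, columns=["genotype", "harvest", "dmc"])
    density = pd.DataFrame(
        den_rows, columns=["genotype", "harvest", "t_min", "weight_in_water_g"]
    )
    truth = pd.DataFrame(
        {
            "genotype": [p.genotype_id for p in profiles],
            "group": [p.group for p in profiles],
            "ct_true": [p.ct_true for p in profiles],
            "dmc_true": [p.dmc_true for p in profiles],
            "wab_max": [p.wab_max for p in profiles],
            "wab_tau": [p.wab_tau for p in profiles],
            "swell_alpha": [p.swell_alpha for p in profiles],
        }
    )
    return CampaignData(weights, softening, dmc, density, truth, seed=seed)
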