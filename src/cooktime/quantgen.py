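"""Variance components, broad-sense heritability and BLUP.

Per-harvest repeatability of a phenotyping protocol is summarised by the
one-way random-genotype model with replications as a fixed effect:

    y_ij = mu + rep_j + g_i + e_ij,   g ~ N(0, Vg),  e ~ N(0, Ve)

estimated by Henderson's method III (fitting-constants method of moments):
Ve is the residual mean square after fitting replications and genotypes by
least squares, and Vg = (R(g | mu, rep) - df_g Ve) / c with
c = tr(Z'(I - P_X)Z), which reduces to df_g * r for balanced data.  Closed
form, no iterative-solver ambiguity, and exactly reproducible.

Broad-sense heritability H^2 = Vg / (Vg + Ve) measures how well the
protocol controls experimental error.

Genotype merit across harvests is predicted by BLUP under the crossed
random model y = mu + G + H + GH + e, solved through the dense mixed-model
equations; unknown variance components are estimated by EM-REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "BlupResult",
    "ConvergenceError",
    "heritability",
    "variance_components_oneway",
    "blup_across_harvests",
]


class ConvergenceError(RuntimeError):
    """EM-REML failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: dict):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class VarianceComponents:
    trait: str
    harvest_id: str
    vg: float
    ve: float
    h2: float
    n_genotypes: int
    n_reps: int

    def __post_init__(self) -> None:
        if self.vg < 0 or self.ve < 0:
            raise ValueError("variance components must be >= 0")


@dataclass(frozen=True)
class BlupResult:
    genotype_id: str
    trait: str
    blup_value: float
    raw_mean: float


def heritability(vg: float, ve: float) -> float:
    """Broad-sense heritability H^2 = Vg / (Vg + Ve), clipped to [0, 1]."""
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be >= 0")
    if vg + ve == 0:
        raise ValueError("H^2 undefined: Vg + Ve = 0")
    return float(np.clip(vg / (vg + ve), 0.0, 1.0))


def _design_matrix(labels) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    idx = {lev: k for k, lev in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for row, lab in enumerate(labels):
        Z[row, idx[lab]] = 1.0
    return Z, levels


def variance_components_oneway(
    data: pd.DataFrame,
    trait: str = "value",
    harvest_id: str = "",
    rep_fixed: bool = True,
) -> VarianceComponents:
    """Henderson III variance components for one trait at one harvest.

    ``data`` is tidy with columns genotype, rep, value.  Replication
    effects are removed as fixed by least squares; Ve is the residual mean
    square; Vg comes from the genotype reduction sum of squares with the
    exact trace coefficient (equal to the replicate count when balanced;
    unbalanced data — e.g. genotypes lost to rot — are tolerated).
    Negative Vg estimates are truncated to 0 with a warning.
    """
    required = {"genotype", "rep", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    y = data["value"].to_numpy(dtype=float)
    n = y.size
    genotypes = data["genotype"].to_numpy()
    counts = pd.Series(genotypes).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 genotypes")
    if (counts < 2).all():
        raise ValueError(
            "all genotypes have a single observation: Ve is inestimable"
        )

    X = np.ones((n, 1))
    if rep_fixed and data["rep"].nunique() > 1:
        R, rep_levels = _design_matrix(data["rep"].to_numpy())
        X = np.hstack([X, R[:, 1:]])  # drop first level
    Z, _ = _design_matrix(genotypes)

    XZ = np.hstack([X, Z])
    rank_x = np.linalg.matrix_rank(X)
    rank_full = np.linalg.matrix_rank(XZ)
    df_e = n - rank_full
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom")

    rss_x = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - XZ @ np.linalg.lstsq(XZ, y, rcond=None)[0]) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss_full <= 1e-12 * max(tss, 1.0):  # numerically exact fit
        rss_full = 0.0
    ve = rss_full / df_e

    df_g = rank_full - rank_x
    # c = tr(Z' (I - P_X) Z) via an orthonormal basis of col(X)
    Q, _ = np.linalg.qr(X)
    QtZ = Q.T @ Z
    c = float(np.trace(Z.T @ Z) - np.sum(QtZ * QtZ))
    r_g = rss_x - rss_full
    if r_g <= 1e-12 * max(tss, 1.0):  # genotypes explain nothing
        r_g = 0.0
    vg = (r_g - df_g * ve) / c
    if vg < 0:
        # numerically-zero negatives are clamped silently
        if vg < -1e-9 * max(1.0, ve):
            warnings.warn(
                f"negative Vg estimate ({vg:.4g}) truncated to 0", stacklevel=2
            )
        vg = 0.0
    h2 = heritability(vg, ve) if (vg + ve) > 0 else float("nan")
    return VarianceComponents(
        trait=trait,
        harvest_id=harvest_id,
        vg=float(vg),
        ve=float(ve),
        h2=h2,
        n_genotypes=int(len(counts)),
        n_reps=int(round(counts.mean())),
    )


# --------------------------------------------------------------------------
# BLUP across harvests
# --------------------------------------------------------------------------


class _MME:
    """Mixed-model equations with precomputed normal-equation blocks, so
    repeated solves during EM only redo the diagonal damping."""

    def __init__(self, y, X, Zs):
        self.y = y
        self.p = X.shape[1]
        self.qs = [Z.shape[1] for Z in Zs]
        self.W = np.hstack([X] + list(Zs))
        self.C0 = self.W.T @ self.W
        self.rhs = self.W.T @ y
        self.slices = []
        off = self.p
        for q in self.qs:
            self.slices.append(slice(off, off + q))
            off += q

    def solve(self, variances, ve, method="inv"):
        """Returns (beta, [u_i], [tr(Cinv_ii)], sol, rhs).

        A factor with zero variance is pinned to u = 0 by infinite damping
        (implemented by zeroing its rows/columns and identity diagonal).
        ``method='pinv'`` requests the minimum-norm solution, needed when a
        vanishing residual variance removes the damping that separates the
        intercept from the factor incidences.
        """
        C = self.C0.copy()
        for sl, s2 in zip(self.slices, variances):
            if s2 > 0:
                C[sl, sl] += np.eye(sl.stop - sl.start) * (ve / s2)
        rhs = self.rhs.copy()
        for sl, s2 in zip(self.slices, variances):
            if s2 <= 0:
                C[sl, :] = 0.0
                C[:, sl] = 0.0
                C[sl, sl] = np.eye(sl.stop - sl.start)
                rhs[sl] = 0.0
        Cinv = np.linalg.pinv(C) if method == "pinv" else np.linalg.inv(C)
        sol = Cinv @ rhs
        beta = sol[: self.p]
        us = [sol[sl] if s2 > 0 else np.zeros(sl.stop - sl.start)
              for sl, s2 in zip(self.slices, variances)]
        traces = [
            float(np.trace(Cinv[sl, sl])) if s2 > 0 else 0.0
            for sl, s2 in zip(self.slices, variances)
        ]
        return beta, us, traces, sol, rhs


def blup_across_harvests(
    data: pd.DataFrame,
    components: Optional[Mapping[str, float]] = None,
    trait: str = "value",
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> list[BlupResult]:
    """Genotype BLUPs under y = mu + G + H + GH + e (all random but mu).

    ``data`` is tidy with columns genotype, harvest, value (one record per
    genotype x harvest cell, missing cells tolerated).  ``components`` may
    supply {'vg', 'vh', 'vgh', 've'}; otherwise they are estimated by
    EM-REML iterated to relative change < ``tol`` (or ``max_iter``, after
    which a :class:`ConvergenceError` carrying the last iterate is raised).
    Returns mu + G_hat per genotype together with the raw genotype mean.

    Harvest and interaction terms are dropped automatically when the data
    contain a single harvest.
    """
    required = {"genotype", "harvest", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    data = data.dropna(subset=["value"])
    y = data["value"].to_numpy(dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("no observations")

    Zg, genotypes = _design_matrix(data["genotype"].to_numpy())
    factors = ["vg"]
    Zs = [Zg]
    if data["harvest"].nunique() > 1:
        Zh, _ = _design_matrix(data["harvest"].to_numpy())
        cell = data["genotype"].astype(str) + "\x00" + data["harvest"].astype(str)
        Zgh, _ = _design_matrix(cell.to_numpy())
        factors += ["vh", "vgh"]
        Zs += [Zh, Zgh]

    X = np.ones((n, 1))
    mme = _MME(y, X, Zs)

    if components is not None:
        sigma = [float(components.get(f, 0.0)) for f in factors]
        ve = float(components.get("ve", 0.0))
        ve = max(ve, 1e-12)  # exact-zero residual: no-shrinkage limit
        beta, us, _, _, _ = mme.solve(sigma, ve, method="pinv")
    else:
        # EM-REML starting from an equal split of the total variance
        total = max(float(np.var(y)), 1e-12)
        sigma = [total / (len(factors) + 1)] * len(factors)
        ve = total / (len(factors) + 1)
        converged = False
        for _ in range(max_iter):
            beta, us, traces, sol, rhs = mme.solve(sigma, ve)
            new_sigma = [
                float((u @ u + ve * tr_c) / q) if s2 > 0 else 0.0
                for u, tr_c, s2, q in zip(us, traces, sigma, mme.qs)
            ]
            new_ve = float((y @ y - sol @ rhs) / (n - X.shape[1]))
            new_ve = max(new_ve, 1e-12)
            rel = max(
                abs(a - b) / max(abs(b), 1e-12)
                for a, b in zip(new_sigma + [new_ve], sigma + [ve])
            )
            sigma, ve = new_sigma, new_ve
            if rel < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"EM-REML did not converge in {max_iter} iterations "
                f"(last relative change {rel:.3g})",
                last_iterate=dict(zip(factors + ["ve"], sigma + [ve])),
            )
        beta, us, _, _, _ = mme.solve(sigma, ve, method="pinv")

    mu = float(beta[0])
    g_hat = us[0]
    raw = data.groupby("genotype")["value"].mean()
    results = []
    for k, g in enumerate(genotypes):
        results.append(
            BlupResult(
                genotype_id=g,
                trait=trait,
                blup_value=mu + float(g_hat[k]),
                raw_mean=float(raw.loc[g]),
            )
        )
    return results
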