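"""Global fitting of titration and kinetic curves.

Two isotherm families are provided, matching the generative models of
:mod:`flapsm.simulate`:

* the two-state Hill form y = b + a * x^n / (K^n + x^n), with the Hill
  exponent and half-point optionally shared across datasets (global fit);
* the quadratic tight-binding form with ligand depletion, required when
  the probe concentration is comparable to K_D.

Exponential kinetics are fitted either as least-squares monoexponential
decays (ensemble relaxations, e.g. competition dissociation) or as
censoring-aware maximum likelihood on dwell-time samples, where the MLE
is rate = n_events / total observed time.

All least-squares fits run through lmfit with a fixed number of jittered
restarts so results are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from flapsm.simulate import (
    DwellSample,
    TitrationCurve,
    hill_fraction,
    quadratic_bound_fraction,
)

__all__ = ["FitResult", "fit_hill", "fit_binding", "fit_exponential", "bootstrap_se"]

HILL_N_BOUNDS = (0.2, 5.0)  # guards against degenerate cooperativity fits


@dataclass
class FitResult:
    """Parameter estimates with uncertainties from a (global) fit."""

    params: dict[str, float]
    stderr: dict[str, float]
    r_value: float
    residual_sd: float
    converged: bool
    shared: tuple[str, ...] = ()
    datasets: tuple[str, ...] = ()
    n_points: int = 0
    detail: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _as_frames(curves) -> list[pd.DataFrame]:
    if isinstance(curves, (TitrationCurve, pd.DataFrame)):
        curves = [curves]
    frames = []
    for i, c in enumerate(curves):
        df = c.to_frame() if isinstance(c, TitrationCurve) else pd.DataFrame(c)
        if "dataset_id" not in df.columns:
            df = df.assign(dataset_id=f"curve{i}")
        frames.append(df)
    return frames


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    """Mean signal per concentration with inverse-variance weights.

    Per-point variances estimated from a handful of replicates are too
    noisy to weight by (they inflate the estimator variance well above
    the information bound), so the replicate scatter is pooled across
    concentrations into one variance per dataset: points keep equal
    weights within a dataset while datasets with noisier replicates are
    down-weighted in a global fit.  Externally supplied per-point
    standard errors (column ``signal_se``, e.g. bootstrap SEs from
    single-molecule averaging) are trusted as-is.
    """
    g = df.groupby("concentration")["signal"]
    out = pd.DataFrame({"y": g.mean(), "sd": g.std(ddof=1), "n": g.size()}).reset_index()
    if "signal_se" in df.columns:
        se = df.groupby("concentration")["signal_se"].mean().reset_index(drop=True)
        out["weight"] = np.where(se > 0, 1.0 / se.clip(lower=se[se > 0].min()), 1.0)
    elif (out["n"] >= 3).all() and (out["sd"] > 0).all():
        pooled_var = float(np.average(out["sd"] ** 2, weights=out["n"] - 1))
        out["weight"] = np.sqrt(out["n"]) / np.sqrt(pooled_var)
    else:
        out["weight"] = 1.0
    return out


def _correlation(y: np.ndarray, yhat: np.ndarray) -> float:
    if len(y) < 2 or np.std(y) == 0 or np.std(yhat) == 0:
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def _global_titration_fit(
    frames: list[pd.DataFrame],
    kind: str,
    share: Sequence[str],
    probe_total,
    seed: int,
    fix_n: float | None = None,
) -> FitResult:
    share = tuple(share)
    agg = [_aggregate(df) for df in frames]
    names = [str(df["dataset_id"].iloc[0]) for df in frames]
    for a in agg:
        if a["concentration"].nunique() < 4:
            raise ValueError("need >= 4 distinct concentrations per curve")

    if kind == "binding":
        if probe_total is None:
            raise ValueError("probe_total is required for the tight-binding model")
        probes = (
            list(probe_total)
            if isinstance(probe_total, (list, tuple, np.ndarray))
            else [float(probe_total)] * len(frames)
        )

    x_all = np.concatenate([a["concentration"].to_numpy() for a in agg])
    x_pos = x_all[x_all > 0]
    k_init = float(np.median(x_pos)) if len(x_pos) else 1.0

    shared_kd = "kd" in share or "K_D" in share
    share_n = fix_n is not None or "n" in share
    share_k = "half_point" in share

    def build_params(jitter: np.ndarray) -> lmfit.Parameters:
        p = lmfit.Parameters()
        if kind == "hill":
            if fix_n is not None:
                p.add("n", value=fix_n, vary=False)
            elif share_n:
                p.add("n", value=1.0 * jitter[0], min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1])
            if share_k:
                p.add("half_point", value=k_init * jitter[1], min=1e-12)
        elif shared_kd:
            p.add("kd", value=k_init * jitter[1], min=1e-12)
        for i, a in enumerate(agg):
            y = a["y"].to_numpy()
            p.add(f"baseline_{i}", value=float(y[np.argmin(a['concentration'])]))
            amp0 = float(y[np.argmax(a["concentration"])] - y[np.argmin(a["concentration"])])
            p.add(f"amplitude_{i}", value=amp0 if amp0 != 0 else 1e-3)
            if kind == "hill" and not share_n:
                p.add(f"n_{i}", value=1.0 * jitter[0], min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1])
            if kind == "hill" and not share_k:
                p.add(f"half_point_{i}", value=k_init * jitter[1], min=1e-12)
            if kind == "binding" and not shared_kd:
                p.add(f"kd_{i}", value=k_init * jitter[1], min=1e-12)
        return p

    def residual(p: lmfit.Parameters) -> np.ndarray:
        res = []
        for i, a in enumerate(agg):
            x = a["concentration"].to_numpy()
            if kind == "hill":
                n = p["n"].value if share_n else p[f"n_{i}"].value
                k = p["half_point"].value if share_k else p[f"half_point_{i}"].value
                frac = hill_fraction(x, k, n)
            else:
                k = p["kd"].value if shared_kd else p[f"kd_{i}"].value
                frac = quadratic_bound_fraction(x, probes[i], k)
            yhat = p[f"baseline_{i}"].value + p[f"amplitude_{i}"].value * frac
            res.append((a["y"].to_numpy() - yhat) * a["weight"].to_numpy())
        return np.concatenate(res)

    # 10 jittered restarts, best-of, deterministic given seed
    rng = np.random.default_rng(seed)
    jitters = np.vstack([[1.0, 1.0], np.exp(rng.normal(0.0, 0.4, size=(9, 2)))])
    best = None
    for j in jitters:
        try:
            out = lmfit.minimize(residual, build_params(j), method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise RuntimeError("titration fit did not converge")

    p = best.params
    y_all, yhat_all = [], []
    for i, a in enumerate(agg):
        x = a["concentration"].to_numpy()
        if kind == "hill":
            n = p["n"].value if share_n else p[f"n_{i}"].value
            k = p["half_point"].value if share_k else p[f"half_point_{i}"].value
            frac = hill_fraction(x, k, n)
        else:
            k = p["kd"].value if shared_kd else p[f"kd_{i}"].value
            frac = quadratic_bound_fraction(x, probes[i], k)
        yhat_all.append(p[f"baseline_{i}"].value + p[f"amplitude_{i}"].value * frac)
        y_all.append(a["y"].to_numpy())
    y_all = np.concatenate(y_all)
    yhat_all = np.concatenate(yhat_all)

    params = {k: float(v.value) for k, v in p.items()}
    stderr = {k: float(v.stderr) if v.stderr is not None else float("nan") for k, v in p.items()}
    return FitResult(
        params=params,
        stderr=stderr,
        r_value=_correlation(y_all, yhat_all),
        residual_sd=float(np.std(y_all - yhat_all, ddof=1)),
        converged=bool(best.success),
        shared=share,
        datasets=tuple(names),
        n_points=len(y_all),
        detail={"redchi": float(best.redchi), "nfev": int(best.nfev)},
    )


def fit_hill(
    curves,
    share: Sequence[str] = ("n", "half_point"),
    seed: int = 0,
    fix_n: float | None = None,
) -> FitResult:
    """Weighted least-squares fit of the two-state Hill form, optionally
    sharing the exponent and/or half-point across datasets.

    With ``fix_n=1`` this reduces to a hyperbolic (non-depleting) binding
    fit.  Baselines and amplitudes are always per-dataset.
    """
    return _global_titration_fit(_as_frames(curves), "hill", share, None, seed, fix_n)


def fit_binding(
    curves,
    probe_total=None,
    share: Sequence[str] = ("kd",),
    seed: int = 0,
) -> FitResult:
    """Quadratic tight-binding (ligand-depletion) global fit.

    ``probe_total`` (nM) may be a scalar applied to every dataset or a
    sequence per dataset; it is a known constant, never fitted.  If
    omitted, the probe totals stored on the TitrationCurve objects are
    used.
    """
    frames = _as_frames(curves)
    if probe_total is None:
        if isinstance(curves, (TitrationCurve, pd.DataFrame)):
            curves = [curves]
        probe_total = [
            c.probe_total if isinstance(c, TitrationCurve) else None for c in curves
        ]
        if any(p is None for p in probe_total):
            raise ValueError("probe_total must be supplied")
    return _global_titration_fit(frames, "binding", share, probe_total, seed)


def fit_exponential(
    t: np.ndarray | None = None,
    y: np.ndarray | None = None,
    dwells: DwellSample | np.ndarray | None = None,
    censored: np.ndarray | None = None,
    offset: bool = False,
    seed: int = 0,
) -> FitResult:
    """Monoexponential rate from a decay curve or a dwell-time sample.

    Curve mode (``t``, ``y``): least squares on y = A * exp(-k t) (+ c if
    ``offset``); needs >= 5 points.

    Dwell mode (``dwells`` with optional ``censored`` flags, or a
    :class:`DwellSample`): censoring-aware maximum likelihood,
    rate = n_uncensored / sum(observed times), SE = rate / sqrt(n_events);
    needs >= 20 dwells and at least one uncensored event.
    """
    if dwells is not None:
        if isinstance(dwells, DwellSample):
            times = np.asarray(dwells.times, dtype=float)
            cens = np.asarray(dwells.censored, dtype=bool)
        else:
            times = np.asarray(dwells, dtype=float)
            cens = (
                np.zeros(len(times), dtype=bool)
                if censored is None
                else np.asarray(censored, dtype=bool)
            )
        if len(times) < 20:
            raise ValueError("need >= 20 dwells")
        n_events = int((~cens).sum())
        if n_events == 0:
            raise ValueError("all dwells censored: rate not identifiable")
        total_time = float(times.sum())
        rate = n_events / total_time
        se = rate / np.sqrt(n_events)
        return FitResult(
            params={"rate": rate},
            stderr={"rate": se},
            r_value=float("nan"),
            residual_sd=float("nan"),
            converged=True,
            n_points=len(times),
            detail={"n_events": n_events, "n_censored": int(cens.sum()),
                    "total_time": total_time},
        )

    if t is None or y is None:
        raise ValueError("provide either (t, y) or dwells")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need >= 5 points for a curve fit")

    span = t.max() - t.min()
    k0 = 1.0 / span if span > 0 else 1.0
    p = lmfit.Parameters()
    p.add("amplitude", value=float(y[0] - (y[-1] if offset else 0.0)))
    p.add("rate", value=k0, min=0.0)
    if offset:
        p.add("offset", value=float(y[-1]))

    def residual(p):
        yhat = p["amplitude"].value * np.exp(-p["rate"].value * t)
        if offset:
            yhat = yhat + p["offset"].value
        return y - yhat

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        raise RuntimeError("exponential fit did not converge")
    yhat = y - residual(out.params)
    params = {k: float(v.value) for k, v in out.params.items()}
    stderr = {
        k: float(v.stderr) if v.stderr is not None else float("nan")
        for k, v in out.params.items()
    }
    return FitResult(
        params=params,
        stderr=stderr,
        r_value=_correlation(y, yhat),
        residual_sd=float(np.std(y - yhat, ddof=1)),
        converged=True,
        n_points=len(t),
        detail={"redchi": float(out.redchi)},
    )


def bootstrap_se(
    curves,
    fit_func,
    params: Sequence[str],
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, float]:
    """Bootstrap standard errors for a titration fit.

    Replicate measurements are resampled with replacement within each
    (dataset, concentration) cell and the fit repeated ``n_boot`` times;
    the standard deviation of each requested parameter across draws is
    returned.  For well-conditioned data these bracket the least-squares
    standard errors.
    """
    frames = _as_frames(curves)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {p: [] for p in params}
    for b in range(n_boot):
        resampled = []
        for df in frames:
            parts = []
            for _, grp in df.groupby("concentration"):
                idx = rng.integers(0, len(grp), size=len(grp))
                parts.append(grp.iloc[idx])
            resampled.append(pd.concat(parts, ignore_index=True))
        try:
            res = fit_func(resampled, seed=seed, **fit_kwargs)
        except (RuntimeError, ValueError):
            continue
        for p in params:
            draws[p].append(res.params[p])
    return {p: float(np.std(v, ddof=1)) if len(v) > 2 else float("nan")
            for p, v in draws.items()}
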