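"""RPPM dilution-series protein quantification.

A reverse-phase protein microarray prints each plasma sample as a serial
1:1 dilution series; after background correction the net intensity vs.
dilution response is fit, on a log-log scale, by a five-parameter
logistic.  The workflow implemented here:

1. background-correct and filter spots (SNR < 2 or net fluorescence < 10
   are indiscernible from background and excluded);
2. fit a slide-wide 5PL *master curve* to all usable points pooled on a
   common dilution-step axis;
3. reject outliers by a ROUT-style false-discovery-rate test (Q = 0.01)
   and refine the master curve;
4. fit each local block of samples jointly, sharing the asymptotes,
   Hill slope and asymmetry across samples (one free position per
   sample), initialized at the master-curve values;
5. read out per-sample protein amount as the y-intercept of the straight
   line through the linear portion of the fitted response.

Spot tables are plain pandas DataFrames with columns
``sample_id, block_id, dilution_step, deposition, raw, background, snr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rmtbi_markers.fivepl import FivePL, eval_5pl, response_band

SPOT_COLUMNS = ("sample_id", "block_id", "dilution_step", "deposition",
                "raw", "background", "snr")

#: parameter bounds for the bounded least-squares fits
_B_BOUNDS = (0.1, 10.0)
_G_BOUNDS = (0.1, 10.0)
_C_PAD = 4.0          # C constrained to data range +/- this many log2 units
_FTOL = 1e-10
_MAX_ITER = 500


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed (insufficient data)."""


class DataError(ValueError):
    """Raised on malformed spot data (non-finite values, missing columns)."""


@dataclass(frozen=True)
class FilterThresholds:
    """Spot exclusion thresholds (strict inequalities) and FDR level."""

    snr_min: float = 2.0
    net_min: float = 10.0
    fdr_q: float = 0.01

    def __post_init__(self) -> None:
        if self.snr_min <= 0 or self.net_min <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")


@dataclass
class DilutionSeries:
    """One sample's usable dilution response.

    ``x`` is log2 relative concentration (step k -> -k, so the undiluted
    printed sample sits at x = 0), ``y`` is log10 mean net intensity
    (replicate depositions averaged).  Points are ordered by increasing
    concentration.
    """

    sample_id: str
    block_id: str
    x: np.ndarray
    y: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.usable = np.asarray(self.usable, bool)
        order = np.argsort(self.x)
        self.x, self.y, self.usable = self.x[order], self.y[order], self.usable[order]

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass
class MasterCurveFit:
    params: FivePL
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray          # over all points, under final params
    outlier_mask: np.ndarray       # True = excluded from the final fit
    n_refinement_rounds: int = 0
    converged: bool = True

    @property
    def kept_rss(self) -> float:
        r = self.residuals[~self.outlier_mask]
        return float(np.dot(r, r))


@dataclass
class LocalBlockFit:
    block_id: str
    shared: FivePL                         # C is the mean position, informational
    positions: dict[str, float]            # sample_id -> C_i
    rss: float
    converged: bool = True

    def sample_params(self, sample_id: str) -> FivePL:
        s = self.shared
        return FivePL(A=s.A, D=s.D, C=self.positions[sample_id], B=s.B, G=s.G)


@dataclass
class Quantification:
    sample_id: str
    linear_slope: float      # log10 AU per log2 concentration
    y_intercept: float       # log10 AU at dilution step 0
    n_points_used: int
    usable: bool = True


# ---------------------------------------------------------------------------
# filtering

def compute_net_fluorescence(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``net`` column: raw fluorescence minus local background.

    Net values may be negative; the ``net_min`` filter removes them
    downstream.  Non-finite raw/background values raise
    :class:`DataError`.
    """
    missing = [c for c in ("raw", "background") if c not in table.columns]
    if missing:
        raise DataError(f"spot table missing columns: {missing}")
    raw = table["raw"].to_numpy(float)
    bg = table["background"].to_numpy(float)
    if not (np.isfinite(raw).all() and np.isfinite(bg).all()):
        raise DataError("non-finite raw or background fluorescence")
    out = table.copy()
    out["net"] = raw - bg
    return out


def filter_spots(table: pd.DataFrame,
                 thresholds: FilterThresholds = FilterThresholds(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition spots into (kept, excluded).

    A spot is excluded iff ``snr < snr_min`` or ``net < net_min`` (both
    strict, matching the printed "<" criteria); boundary values are
    kept.  The two outputs are disjoint and their union is the input.
    """
    if "net" not in table.columns:
        table = compute_net_fluorescence(table)
    if len(table) == 0:
        return table, table
    snr = table["snr"].to_numpy(float)
    if "snr" in table.columns and not np.isfinite(snr).all():
        raise DataError("non-finite SNR values")
    bad = (snr < thresholds.snr_min) | (table["net"].to_numpy(float) < thresholds.net_min)
    return table.loc[~bad], table.loc[bad]


def build_series(kept: pd.DataFrame) -> list[DilutionSeries]:
    """Collapse filtered spots into per-sample dilution series.

    Replicate depositions are averaged (in linear AU, after filtering);
    the series ordinate is log10 of the mean net intensity and the
    abscissa is -dilution_step (log2 relative concentration).
    """
    series: list[DilutionSeries] = []
    for (sid, bid), grp in kept.groupby(["sample_id", "block_id"], sort=True):
        mean_net = grp.groupby("dilution_step")["net"].mean()
        steps = mean_net.index.to_numpy(float)
        net = mean_net.to_numpy(float)
        usable = net > 0
        y = np.full_like(net, np.nan)
        y[usable] = np.log10(net[usable])
        series.append(DilutionSeries(sample_id=str(sid), block_id=str(bid),
                                     x=-steps, y=y, usable=usable))
    return series


def pool_points(series: list[DilutionSeries]) -> tuple[np.ndarray, np.ndarray]:
    """All usable points pooled on the common dilution-step axis."""
    xs, ys = [], []
    for s in series:
        xs.append(s.x[s.usable])
        ys.append(s.y[s.usable])
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# master curve

def _initial_guess(x: np.ndarray, y: np.ndarray) -> FivePL:
    """Deterministic initialization from data quantiles."""
    a = float(np.quantile(y, 0.02))
    d = float(np.quantile(y, 0.98))
    if d - a < 1e-6:
        d = a + 1e-3
    mid = 0.5 * (a + d)
    c = float(x[np.argmin(np.abs(y - mid))])
    return FivePL(A=a, D=d, C=c, B=1.0, G=1.0)


def _ls_bounds(x: np.ndarray, n_positions: int = 1) -> tuple[np.ndarray, np.ndarray]:
    ylo, yhi = -np.inf, np.inf
    clo, chi = float(x.min()) - _C_PAD, float(x.max()) + _C_PAD
    lo = [ylo, ylo, _B_BOUNDS[0], _G_BOUNDS[0]] + [clo] * n_positions
    hi = [yhi, yhi, _B_BOUNDS[1], _G_BOUNDS[1]] + [chi] * n_positions
    return np.array(lo), np.array(hi)


def _fivepl_residuals(v: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = FivePL(A=v[0], D=v[1], B=v[2], G=v[3], C=v[4])
    return eval_5pl(x, p) - y


def fit_master_curve(x: np.ndarray, y: np.ndarray,
                     init: FivePL | None = None) -> MasterCurveFit:
    """Least-squares 5PL fit to all pooled slide points in log-log space.

    Requires at least 8 usable points spanning at least 3 distinct
    dilution positions.  Non-convergence is flagged on the result, never
    silent.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 8 or len(np.unique(x)) < 3:
        raise FitError(
            f"master fit needs >= 8 points over >= 3 dilution positions; "
            f"got {len(x)} points, {len(np.unique(x))} positions")
    p0 = init if init is not None else _initial_guess(x, y)
    v0 = np.array([p0.A, p0.D, p0.B, p0.G, p0.C])
    lo, hi = _ls_bounds(x)
    v0 = np.clip(v0, lo + 1e-9, hi - 1e-9)
    res = optimize.least_squares(
        _fivepl_residuals, v0, bounds=(lo, hi), args=(x, y),
        method="trf", ftol=_FTOL, xtol=_FTOL, gtol=_FTOL,
        max_nfev=_MAX_ITER * (len(v0) + 1))
    params = FivePL(A=res.x[0], D=res.x[1], B=res.x[2], G=res.x[3], C=res.x[4])
    residuals = eval_5pl(x, params) - y
    return MasterCurveFit(params=params, x=x, y=y, residuals=residuals,
                          outlier_mask=np.zeros(len(x), bool),
                          converged=bool(res.status > 0))


# ---------------------------------------------------------------------------
# FDR (ROUT-style) outlier rejection

def fdr_outlier_mask(residuals: np.ndarray, q: float = 0.01,
                     n_params: int = 5) -> np.ndarray:
    """ROUT-style FDR outlier detection on fit residuals.

    The robust scale is the 68.27th percentile of |residuals| (the RSDR:
    for Gaussian residuals this percentile estimates sigma without being
    inflated by outliers).  Each point gets a two-sided t p-value with
    ``n - n_params`` degrees of freedom, and the Benjamini-Hochberg
    step-up at rate ``q`` flags the outliers.

    All-zero residuals yield an empty mask.
    """
    r = np.asarray(residuals, float)
    n = len(r)
    if n < 10:
        raise FitError(f"FDR outlier test needs >= 10 residuals, got {n}")
    scale = float(np.percentile(np.abs(r), 68.27))
    mask = np.zeros(n, bool)
    if scale < 1e-12:
        # (near-)perfect fit: only residuals far beyond numerical noise
        # can be outliers (1e-6 log10 is ~0.0002% in intensity)
        mask[np.abs(r) > 1e-6] = True
        return mask
    df = max(n - n_params, 1)
    t = np.abs(r) / scale
    p = 2.0 * stats.t.sf(t, df)
    # Benjamini-Hochberg step-up
    order = np.argsort(p)
    thresh = q * np.arange(1, n + 1) / n
    below = p[order] <= thresh
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        mask[order[: k + 1]] = True
    return mask


def refine_master(fit: MasterCurveFit,
                  thresholds: FilterThresholds = FilterThresholds(),
                  max_rounds: int = 5) -> MasterCurveFit:
    """Alternate FDR outlier exclusion and refitting of the master curve.

    Stops when the outlier set is unchanged or after ``max_rounds``
    rounds (flagged non-converged).  Each refit is initialized at the
    previous parameters, so the residual sum of squares over the kept
    points never increases.
    """
    if not fit.converged:
        raise FitError("cannot refine a non-converged master fit")
    params = fit.params
    x, y = fit.x, fit.y
    mask = np.zeros(len(x), bool)
    rounds = 0
    converged = False
    for rounds in range(1, max_rounds + 1):
        residuals = eval_5pl(x, params) - y
        new_mask = fdr_outlier_mask(residuals, q=thresholds.fdr_q)
        if np.array_equal(new_mask, mask) and rounds > 1:
            converged = True
            break
        mask = new_mask
        if mask.all():
            raise FitError("all points flagged as outliers; cannot refit")
        refit = fit_master_curve(x[~mask], y[~mask], init=params)
        params = refit.params
        if not mask.any():
            converged = True
            break
    residuals = eval_5pl(x, params) - y
    return MasterCurveFit(params=params, x=x, y=y, residuals=residuals,
                          outlier_mask=mask, n_refinement_rounds=rounds,
                          converged=converged)


# ---------------------------------------------------------------------------
# local block fits

def _block_residuals(v: np.ndarray, series: list[DilutionSeries]) -> np.ndarray:
    out = []
    for i, s in enumerate(series):
        p = FivePL(A=v[0], D=v[1], B=v[2], G=v[3], C=v[4 + i])
        out.append(eval_5pl(s.x[s.usable], p) - s.y[s.usable])
    return np.concatenate(out)


def fit_local_block(block_series: list[DilutionSeries],
                    master: FivePL) -> LocalBlockFit:
    """Joint shared-parameter 5PL fit for one block of samples.

    The asymptotes A and D, Hill slope B, and asymmetry G are shared
    across the samples of the block; each sample keeps one free position
    C_i.  All parameters are initialized at the master-curve values.  A
    block with a single sample degenerates to an ordinary per-sample fit.
    """
    if not block_series:
        raise FitError("empty block")
    for s in block_series:
        if s.n_usable < 3:
            raise FitError(
                f"sample {s.sample_id}: {s.n_usable} usable points (< 3)")
    block_id = block_series[0].block_id
    m = len(block_series)
    v0 = np.concatenate([[master.A, master.D, master.B, master.G],
                         np.full(m, master.C)])
    all_x = np.concatenate([s.x[s.usable] for s in block_series])
    lo, hi = _ls_bounds(all_x, n_positions=m)
    v0 = np.clip(v0, lo + 1e-9, hi - 1e-9)
    res = optimize.least_squares(
        _block_residuals, v0, bounds=(lo, hi), args=(block_series,),
        method="trf", ftol=_FTOL, xtol=_FTOL, gtol=_FTOL,
        max_nfev=_MAX_ITER * (len(v0) + 1))
    shared = FivePL(A=res.x[0], D=res.x[1], B=res.x[2], G=res.x[3],
                    C=float(np.mean(res.x[4:])))
    positions = {s.sample_id: float(res.x[4 + i])
                 for i, s in enumerate(block_series)}
    return LocalBlockFit(block_id=block_id, shared=shared,
                         positions=positions, rss=float(2 * res.cost),
                         converged=bool(res.status > 0))


# ---------------------------------------------------------------------------
# y-intercept quantification

def quantify_sample(series: DilutionSeries, local: LocalBlockFit,
                    band: tuple[float, float] = (0.25, 0.75)) -> Quantification:
    """Linear-portion y-intercept readout for one sample.

    The linear portion is the set of observed points whose *fitted*
    response lies within ``band`` (default [25%, 75%]) of the
    asymptote-to-asymptote range.  An ordinary least-squares line through
    those points in (log2 concentration, log10 intensity) gives the
    slope, and its value at dilution step 0 (x = 0) is the y-intercept
    indexing the amount of protein.  With fewer than 2 linear-portion
    points the quantification is marked unusable rather than
    extrapolated.
    """
    p = local.sample_params(series.sample_id)
    x = series.x[series.usable]
    y = series.y[series.usable]
    ylo, yhi = response_band(p, *band)
    fitted = eval_5pl(x, p)
    sel = (fitted >= ylo) & (fitted <= yhi)
    if sel.sum() < 2:
        return Quantification(sample_id=series.sample_id, linear_slope=np.nan,
                              y_intercept=np.nan, n_points_used=int(sel.sum()),
                              usable=False)
    slope, intercept = np.polyfit(x[sel], y[sel], 1)
    return Quantification(sample_id=series.sample_id,
                          linear_slope=float(slope),
                          y_intercept=float(intercept),
                          n_points_used=int(sel.sum()))


# ---------------------------------------------------------------------------
# slide-level driver

@dataclass
class SlideResult:
    master: MasterCurveFit
    blocks: dict[str, LocalBlockFit]
    quantifications: pd.DataFrame
    excluded: pd.DataFrame = field(repr=False, default=None)


def quantify_slide(spots: pd.DataFrame,
                   thresholds: FilterThresholds = FilterThresholds(),
                   band: tuple[float, float] = (0.25, 0.75)) -> SlideResult:
    """Full RPPM workflow for one slide: filter, master fit + FDR
    refinement, per-block shared-parameter fits, y-intercept readout."""
    table = compute_net_fluorescence(spots)
    kept, excluded = filter_spots(table, thresholds)
    series = build_series(kept)
    x, y = pool_points(series)
    master = refine_master(fit_master_curve(x, y), thresholds)

    blocks: dict[str, LocalBlockFit] = {}
    rows = []
    by_block: dict[str, list[DilutionSeries]] = {}
    for s in series:
        by_block.setdefault(s.block_id, []).append(s)
    for bid in sorted(by_block):
        usable = [s for s in by_block[bid] if s.n_usable >= 3]
        skipped = [s for s in by_block[bid] if s.n_usable < 3]
        for s in skipped:
            warnings.warn(f"sample {s.sample_id}: only {s.n_usable} usable "
                          "points, skipped", stacklevel=2)
        if not usable:
            continue
        fit = fit_local_block(usable, master.params)
        blocks[bid] = fit
        for s in usable:
            q = quantify_sample(s, fit, band=band)
            rows.append({"sample_id": q.sample_id, "block_id": bid,
                         "linear_slope": q.linear_slope,
                         "y_intercept": q.y_intercept,
                         "n_points_used": q.n_points_used,
                         "usable": q.usable})
    quant = pd.DataFrame(rows)
    return SlideResult(master=master, blocks=blocks, quantifications=quant,
                       excluded=excluded)


def summarize_groups(quant: pd.DataFrame, groups: pd.Series | dict,
                     value: str = "y_intercept") -> pd.DataFrame:
    """Per-group mean +/- SEM of y-intercepts (the reported readout)."""
    df = quant.copy()
    if isinstance(groups, dict):
        df["group"] = df["sample_id"].map(groups)
    else:
        df["group"] = df["sample_id"].map(dict(groups))
    out = (df.groupby("group")[value]
             .agg(n="count", mean="mean",
                  sem=lambda v: 0.0 if len(v) < 2 else float(np.std(v, ddof=1) / np.sqrt(len(v))))
             .reset_index())
    return out
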