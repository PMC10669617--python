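"""Core model mathematics and the gradient-descent parameter fit.

The model treats each region's measured BOLD time series as its total
input signaling, the weighted sum of the outputs of its afferent regions
plus any latent input:

    S_input  = M_input  * S_output
    S_output = M_output * S_output

The second equation is an eigenvalue problem: because the latent rows of
``M_output`` form an identity block, the matrix always has one eigenvector
of eigenvalue 1 per latent input.  Scaling each such eigenvector to unit
value at its latent row gives ``M_eigv``; any latent time courses ``L``
then propagate through the network as ``S_output = M_eigv L`` and the
modeled regional inputs are ``S_input = M_input M_eigv L``.

Fitting proceeds in two nested stages.  Given candidate D/DB values, the
latent time courses have a closed-form least-squares solution against the
measured data ``S_BOLD`` (variable latents only; a fixed latent contributes
amplitude x template, subtracted beforehand).  The D/DB values themselves,
plus fixed-latent amplitudes, are found by multi-start finite-difference
gradient descent on the squared-error objective with an L1 penalty on the
DB values that prefers the sparsest network compatible with the data.

Goodness of fit is summarized by the residual sum of squares and by R^2
measures expressed as explained-variance fractions: ``r2_total`` pools all
regions, ``r2_per_region`` treats each region separately, ``r2_average``
is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import ConnectionMatrices, NetworkModel, build_matrices, validate_network

__all__ = [
    "SAPMError",
    "UnstableNetworkError",
    "DegenerateModelError",
    "FitFailureError",
    "BoldDataset",
    "FitMetrics",
    "LatentBasis",
    "FitConfig",
    "SAPMFit",
    "latent_basis",
    "solve_latent_timecourses",
    "forward_signals",
    "fit_metrics",
    "normalize_region_variance",
    "fit_sapm",
]


class SAPMError(Exception):
    """Base class for model/fit errors."""


class UnstableNetworkError(SAPMError):
    """(I - region block) is singular or near-singular: latent inputs
    cannot propagate to a finite steady response."""


class DegenerateModelError(SAPMError):
    """The latent design matrix is rank deficient (collinear latents)."""


class FitFailureError(SAPMError):
    """No gradient-descent start produced a finite objective."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class BoldDataset:
    """Region-averaged BOLD time series in percent-signal-change units.

    ``data`` is (n_regions, T) over the run-concatenated time axis; ``runs``
    lists (start, length) pairs partitioning 0..T; ``regions`` must match a
    model's region list exactly and in order when the two are combined.
    """

    data: np.ndarray
    runs: list[tuple[int, int]]
    regions: list[str]
    participant: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldDataset.data must be 2-D (regions x time)")
        if len(self.regions) != self.data.shape[0]:
            raise ValueError("region names do not match the number of data rows")
        total = sum(length for _, length in self.runs)
        if total != self.data.shape[1]:
            raise ValueError(
                f"run lengths sum to {total} but the data have {self.data.shape[1]} volumes"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def check_alignment(self, model: NetworkModel) -> None:
        if list(self.regions) != list(model.regions):
            raise ValueError(
                "dataset regions do not match the model regions "
                f"(data: {self.regions}, model: {model.regions})"
            )


@dataclass
class FitMetrics:
    err_ssqd: float
    r2_total: float
    r2_average: float
    r2_per_region: dict[str, float]
    excluded_regions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "err_ssqd": self.err_ssqd,
            "r2_total": self.r2_total,
            "r2_average": self.r2_average,
            "r2_per_region": dict(self.r2_per_region),
            "excluded_regions": list(self.excluded_regions),
        }


@dataclass
class LatentBasis:
    """Unit-eigenvalue eigenvectors of M_output, one column per latent.

    Column k is scaled so the entry at latent k's row equals 1 and is zero
    at every other latent row; it describes how a unit of latent-k drive
    propagates to every node's output.
    """

    m_eigv: np.ndarray  # (N, n_latents)
    latent_names: list[str]


@dataclass
class FitConfig:
    """Gradient-descent settings.

    The exploration stage runs ``n_starts`` random initializations for
    ``explore_iters`` iterations each; the best start (lowest residual
    error, ties to the lowest start index) continues for up to
    ``refine_iters`` further iterations.  ``lambda_l1`` weights the L1
    penalty on DB values; when None it is set to ``l1_fraction`` times the
    residual error at the first start's initial point.  The default
    fraction keeps the penalty a tie-break well below the error term:
    larger weights (1e-3 and above) soft-threshold most DB values to a
    common near-zero point, which collapses the across-dataset DB
    distributions that group inference and null calibration rely on.
    Initialization ranges reflect that D values are
    typically near 1 while DB values are small and of either sign.
    """

    n_starts: int = 15
    explore_iters: int = 15
    refine_iters: int = 250
    lambda_l1: float | None = None
    l1_fraction: float = 1e-4
    d_init: tuple[float, float] = (0.5, 1.5)
    db_init: tuple[float, float] = (-0.2, 0.2)
    amp_init: tuple[float, float] = (0.0, 1.0)
    fd_step: float = 1e-3
    step_init: float = 0.1
    step_floor: float = 1e-6
    d_floor: float = 1e-2
    normalize_variance: bool = True
    seed: int = 0
    # Optional map connection -> D value; listed connections keep that D
    # and are excluded from the descent.  Joint (D, DB) estimation from a
    # single dataset is scale-degenerate (a region's output can be
    # rescaled into its consumers' D values), so sensitivity analyses and
    # recovery harnesses can pin the input weightings and estimate DB
    # conditional on them.
    freeze_d: dict | None = None


@dataclass
class SAPMFit:
    """Result of one model fit to one dataset."""

    d_values: dict[tuple[str, str], float]
    db_values: dict[tuple[str, str], float]
    b_values: dict[tuple[str, str], float]
    fixed_latent_amplitudes: dict[str, float]
    latent_timecourses: np.ndarray  # (n_latents, T)
    s_output: np.ndarray  # (N, T)
    s_input: np.ndarray  # (n_regions, T)
    metrics: FitMetrics
    convergence: dict
    regions: list[str]
    latent_names: list[str]
    connections: list[tuple[str, str]]
    scale_factors: dict[str, float] = field(default_factory=dict)

    def db_array(self) -> np.ndarray:
        return np.array([self.db_values[c] for c in self.connections])

    def d_array(self) -> np.ndarray:
        return np.array([self.d_values[c] for c in self.connections])

    def d_values_original_units(self) -> dict[tuple[str, str], float]:
        """D values referred to the unscaled data.

        When the fit ran on variance-normalized data (region r multiplied
        by factor f_r), the equivalent fit of the raw data divides each
        connection's D value by its target region's factor; DB values are
        unaffected by the scaling.
        """
        return {
            (src, tgt): v / self.scale_factors.get(tgt, 1.0)
            for (src, tgt), v in self.d_values.items()
        }


# ---------------------------------------------------------------------------
# Latent basis and forward model
# ---------------------------------------------------------------------------


def latent_basis(matrices: ConnectionMatrices, cond_limit: float = 1e12) -> LatentBasis:
    """Closed-form unit-eigenvalue eigenvector per latent input.

    Writing the region block of M_output as A and latent k's region column
    as a_k, the region part of eigenvector k solves x = A x + a_k, i.e.
    x = (I - A)^-1 a_k; the latent part is the k-th unit vector.  Raises
    :class:`UnstableNetworkError` when (I - A) is singular or its condition
    number exceeds ``cond_limit``.
    """
    nr = matrices.n_regions
    nl = matrices.n_latents
    a = matrices.m_output[:nr, :nr]
    lat_cols = matrices.m_output[:nr, nr:]
    system = np.eye(nr) - a
    cond = np.linalg.cond(system)
    if not np.isfinite(cond) or cond > cond_limit:
        raise UnstableNetworkError(
            f"(I - region block) has condition number {cond:.3g} (limit {cond_limit:.3g})"
        )
    x = np.linalg.solve(system, lat_cols)
    m_eigv = np.vstack([x, np.eye(nl)])
    return LatentBasis(m_eigv=m_eigv, latent_names=list(matrices.latent_names))


def forward_signals(
    matrices: ConnectionMatrices, basis: LatentBasis, latent_timecourses: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate latent time courses: S_output = M_eigv L, S_input = M_input S_output."""
    latents = np.atleast_2d(np.asarray(latent_timecourses, dtype=float))
    if latents.shape[0] != basis.m_eigv.shape[1]:
        raise ValueError(
            f"latent time courses have {latents.shape[0]} rows but the basis "
            f"has {basis.m_eigv.shape[1]} latents"
        )
    s_output = basis.m_eigv @ latents
    s_input = matrices.m_input @ s_output
    return s_output, s_input


def solve_latent_timecourses(
    matrices: ConnectionMatrices,
    basis: LatentBasis,
    data: BoldDataset,
    fixed_amplitudes: Mapping[str, float] | None = None,
    templates: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Least-squares latent time courses given fixed D/DB values.

    Variable latents solve ``L = (M1' M1)^-1 M1' S_BOLD`` with
    ``M1 = M_input M_eigv`` restricted to the variable columns, after the
    fixed-latent contribution (amplitude x template) has been subtracted
    from the data.  Fixed latents are not estimated here: their rows of the
    returned L equal amplitude x template.
    """
    fixed_amplitudes = dict(fixed_amplitudes or {})
    templates = dict(templates or {})
    model = matrices.model
    m1 = matrices.m_input @ basis.m_eigv  # (n_regions, n_latents)
    t_len = data.n_timepoints
    n_lat = matrices.n_latents
    latent_rows = np.zeros((n_lat, t_len))

    fixed_idx, var_idx = [], []
    for k, name in enumerate(matrices.latent_names):
        lat = model.latents[k] if model is not None else None
        is_fixed = (lat is not None and lat.is_fixed) or name in fixed_amplitudes
        (fixed_idx if is_fixed else var_idx).append(k)

    target = data.data.astype(float).copy()
    for k in fixed_idx:
        name = matrices.latent_names[k]
        template = templates.get(name)
        if template is None and model is not None and model.latents[k].template is not None:
            template = _tiled_template(model.latents[k].template, data)
        if template is None:
            raise ValueError(f"fixed latent {name!r} has no template")
        template = np.asarray(template, dtype=float)
        if template.size != t_len:
            raise ValueError(
                f"template for latent {name!r} has {template.size} samples, expected {t_len}"
            )
        amp = float(fixed_amplitudes.get(name, 0.0))
        latent_rows[k] = amp * template
        target -= np.outer(m1[:, k], latent_rows[k])

    if var_idx:
        v = m1[:, var_idx]
        rank = np.linalg.matrix_rank(v)
        if rank < len(var_idx):
            names = [matrices.latent_names[k] for k in var_idx]
            raise DegenerateModelError(
                f"variable-latent columns of M1 are collinear (latents {names})"
            )
        sol, *_ = np.linalg.lstsq(v, target, rcond=None)
        for row, k in enumerate(var_idx):
            latent_rows[k] = sol[row]
    return latent_rows


def _tiled_template(template: np.ndarray, data: BoldDataset) -> np.ndarray:
    """Fit a latent template to a dataset's time axis (tile per run if needed)."""
    template = np.asarray(template, dtype=float)
    t_len = data.n_timepoints
    if template.size == t_len:
        return template
    lengths = {length for _, length in data.runs}
    if lengths == {template.size}:
        return np.tile(template, len(data.runs))
    raise ValueError(
        f"latent template length {template.size} matches neither the total "
        f"time axis ({t_len}) nor the per-run length(s) {sorted(lengths)}"
    )


# ---------------------------------------------------------------------------
# Fit metrics and variance normalization
# ---------------------------------------------------------------------------


def fit_metrics(
    s_input: np.ndarray,
    s_bold: np.ndarray,
    regions: Sequence[str] | None = None,
) -> FitMetrics:
    """Residual error and explained-variance summaries of a modeled fit.

    ``err_ssqd`` sums squared differences over all regions and time points.
    R^2 terms use the data sum of squares as the reference: ``r2_total``
    is 1 - err_ssqd / sum(S_BOLD^2) pooled over regions, and the per-region
    values average into ``r2_average``.  Regions with zero data sum of
    squares have undefined R^2; they are excluded from the average and
    reported in ``excluded_regions``.
    """
    s_input = np.asarray(s_input, dtype=float)
    s_bold = np.asarray(s_bold, dtype=float)
    if s_input.shape != s_bold.shape:
        raise ValueError(f"shape mismatch: {s_input.shape} vs {s_bold.shape}")
    if regions is None:
        regions = [f"region{i}" for i in range(s_bold.shape[0])]

    resid = s_input - s_bold
    ss_res_per = np.sum(resid**2, axis=1)
    ss_dat_per = np.sum(s_bold**2, axis=1)
    err = float(ss_res_per.sum())
    total = float(ss_dat_per.sum())
    r2_total = 1.0 - err / total if total > 0 else (1.0 if err == 0 else -np.inf)

    r2_per: dict[str, float] = {}
    excluded: list[str] = []
    vals = []
    for i, name in enumerate(regions):
        if ss_dat_per[i] > 0:
            r2 = 1.0 - ss_res_per[i] / ss_dat_per[i]
            r2_per[name] = float(r2)
            vals.append(r2)
        else:
            excluded.append(name)
    r2_average = float(np.mean(vals)) if vals else float("nan")
    return FitMetrics(
        err_ssqd=err,
        r2_total=float(r2_total),
        r2_average=r2_average,
        r2_per_region=r2_per,
        excluded_regions=excluded,
    )


def normalize_region_variance(data: BoldDataset) -> tuple[BoldDataset, dict[str, float]]:
    """Scale each region's series so all regions share the mean variance.

    Returns the scaled dataset and the per-region multiplicative factors
    applied to the data.  Because the modeled S_input must scale with the
    data while DB values (and hence S_output) are scale-free, fits on the
    scaled data convert back to original units by dividing each connection's
    D value by its target region's factor; DB values are unaffected.
    """
    variances = np.var(data.data, axis=1)
    zero = np.nonzero(variances == 0)[0]
    if zero.size:
        names = ", ".join(data.regions[i] for i in zero)
        raise ValueError(f"zero-variance region(s): {names}")
    target = variances.mean()
    factors = np.sqrt(target / variances)
    scaled = BoldDataset(
        data=data.data * factors[:, None],
        runs=list(data.runs),
        regions=list(data.regions),
        participant=data.participant,
    )
    return scaled, {name: float(f) for name, f in zip(data.regions, factors)}


# ---------------------------------------------------------------------------
# Fast objective workspace for the gradient descent
# ---------------------------------------------------------------------------


class _Workspace:
    """Preindexed forward model: parameter vector -> (objective, error).

    The parameter vector is [D per connection, DB per connection, one
    amplitude per fixed latent].  Evaluation solves the latent basis in
    closed form, subtracts the fixed-latent contribution, solves the
    variable latents by normal equations, and accumulates the squared
    error.  Any unstable or degenerate parameter point evaluates to +inf
    so the descent simply avoids it.
    """

    def __init__(self, model: NetworkModel, s_bold: np.ndarray, templates: dict[str, np.ndarray]):
        self.model = model
        self.s = np.asarray(s_bold, dtype=float)
        nr, nl = model.n_regions, model.n_latents
        self.nr, self.nl = nr, nl
        self.nc = len(model.connections)
        self.ti = np.array([model.region_index(c.target) for c in model.connections])
        self.si = np.array([model.region_index(c.source) for c in model.connections])
        self.alat = np.zeros((nr, nl))
        for k, lat in enumerate(model.latents):
            self.alat[model.region_index(lat.target_region), k] = 1.0
        self.fixed_idx = [k for k, lat in enumerate(model.latents) if lat.is_fixed]
        self.var_idx = [k for k, lat in enumerate(model.latents) if not lat.is_fixed]
        self.n_fixed = len(self.fixed_idx)
        self.templates = np.array(
            [templates[model.latents[k].name] for k in self.fixed_idx]
        ) if self.fixed_idx else np.zeros((0, self.s.shape[1]))
        self.eye = np.eye(nr)
        self._a = np.zeros((nr, nr))
        self._m = np.zeros((nr, nr))
        self.lambda_l1 = 0.0
        self.n_params = 2 * self.nc + self.n_fixed
        self.free = np.ones(self.n_params, dtype=bool)

    def unpack(self, theta: np.ndarray):
        nc = self.nc
        return theta[:nc], theta[nc : 2 * nc], theta[2 * nc :]

    def error(self, theta: np.ndarray) -> float:
        d, db, amps = self.unpack(theta)
        a = self._a
        a.fill(0.0)
        a[self.ti, self.si] = db
        try:
            x = np.linalg.solve(self.eye - a, self.alat)
        except np.linalg.LinAlgError:
            return np.inf
        if not np.all(np.isfinite(x)):
            return np.inf
        m = self._m
        m.fill(0.0)
        m[self.ti, self.si] = d
        m1 = m @ x + self.alat  # latent weights are 1
        target = self.s
        if self.n_fixed:
            contrib = (amps[:, None] * self.templates)
            fixed_part = m1[:, self.fixed_idx] @ contrib
            target = self.s - fixed_part
        if self.var_idx:
            v = m1[:, self.var_idx]
            g = v.T @ v
            try:
                lv = np.linalg.solve(g, v.T @ target)
            except np.linalg.LinAlgError:
                return np.inf
            resid = v @ lv - target
        else:
            resid = -target
        err = float(np.dot(resid.ravel(), resid.ravel()))
        return err if np.isfinite(err) else np.inf

    def objective(self, theta: np.ndarray) -> float:
        err = self.error(theta)
        if not np.isfinite(err):
            return np.inf
        _, db, _ = self.unpack(theta)
        return err + self.lambda_l1 * float(np.sum(np.abs(db)))

    def gradient(self, theta: np.ndarray, f0: float, h: float) -> np.ndarray:
        g = np.zeros_like(theta)
        work = theta.copy()
        for i in np.nonzero(self.free)[0]:
            orig = work[i]
            work[i] = orig + h
            fi = self.objective(work)
            g[i] = (fi - f0) / h if np.isfinite(fi) else 0.0
            work[i] = orig
        return g

    def clip(self, theta: np.ndarray, d_floor: float) -> np.ndarray:
        out = theta.copy()
        np.clip(out[: self.nc], d_floor, None, out=out[: self.nc])
        return out


def _descend(
    ws: _Workspace,
    theta: np.ndarray,
    max_iters: int,
    step: float,
    cfg: FitConfig,
) -> tuple[np.ndarray, float, float, int]:
    """Finite-difference gradient descent with step-halving line search.

    Returns (theta, objective, final step, iterations used).  The accepted
    objective is non-increasing by construction.
    """
    obj = ws.objective(theta)
    if not np.isfinite(obj):
        return theta, obj, step, 0
    used = 0
    for _ in range(max_iters):
        g = ws.gradient(theta, obj, cfg.fd_step)
        gmax = np.max(np.abs(g))
        if gmax == 0 or not np.isfinite(gmax):
            break
        direction = g / gmax
        improved = False
        while step >= cfg.step_floor:
            cand = ws.clip(theta - step * direction, cfg.d_floor)
            ocand = ws.objective(cand)
            if ocand < obj:
                theta, obj = cand, ocand
                improved = True
                break
            step *= 0.5
        used += 1
        if not improved:
            break
    return theta, obj, step, used


def _normalize_pair(key) -> tuple[str, str]:
    if isinstance(key, str):
        src, tgt = key.split("->", 1)
        return src.strip(), tgt.strip()
    return tuple(key)


def _initial_theta(ws: _Workspace, rng: np.random.Generator, cfg: FitConfig) -> np.ndarray:
    d = rng.uniform(*cfg.d_init, size=ws.nc)
    db = rng.uniform(*cfg.db_init, size=ws.nc)
    amps = rng.uniform(*cfg.amp_init, size=ws.n_fixed)
    return np.concatenate([d, db, amps])


def fit_sapm(
    data: BoldDataset,
    model: NetworkModel,
    config: FitConfig | None = None,
) -> SAPMFit:
    """Estimate D/DB values, latent time courses, and fit metrics.

    Multi-start finite-difference gradient descent on
    ``err_ssqd + lambda_l1 * sum(|DB|)``: ``n_starts`` random starts are
    each descended for ``explore_iters`` iterations, then the start with
    the lowest residual error continues for up to ``refine_iters``
    iterations.  Runs are pooled along the concatenated time axis.  When
    ``config.normalize_variance`` is set the regions are first scaled to a
    common variance and the fit is reported in that space (DB values and
    the R^2 metrics are invariant to the scaling; use
    :meth:`SAPMFit.d_values_original_units` for raw-unit D values).  The
    result is a pure function of the data, model, and config seed.
    """
    cfg = config or FitConfig()
    problems = validate_network(model)
    if problems:
        raise ValueError("invalid network model: " + "; ".join(problems))
    data.check_alignment(model)
    if not np.all(np.isfinite(data.data)):
        raise ValueError("dataset contains non-finite values")

    if cfg.normalize_variance:
        fit_data, factors = normalize_region_variance(data)
    else:
        fit_data, factors = data, {name: 1.0 for name in data.regions}

    templates = {
        lat.name: _tiled_template(lat.template, fit_data)
        for lat in model.latents
        if lat.is_fixed
    }
    ws = _Workspace(model, fit_data.data, templates)

    frozen_d = {}
    if cfg.freeze_d:
        frozen_d = {_normalize_pair(k): float(v) for k, v in cfg.freeze_d.items()}
        pairs = {c.pair for c in model.connections}
        for pair, value in frozen_d.items():
            if pair not in pairs:
                raise ValueError(f"freeze_d names unknown connection {pair}")
            if value <= 0:
                raise ValueError(f"freeze_d value for {pair} must be positive")
        for i, c in enumerate(model.connections):
            if c.pair in frozen_d:
                ws.free[i] = False

    rng = np.random.default_rng(cfg.seed)
    starts = [_initial_theta(ws, rng, cfg) for _ in range(cfg.n_starts)]
    for theta0 in starts:
        for i, c in enumerate(model.connections):
            if c.pair in frozen_d:
                theta0[i] = frozen_d[c.pair]

    if cfg.lambda_l1 is not None:
        ws.lambda_l1 = float(cfg.lambda_l1)
    else:
        base_err = next((e for e in (ws.error(t) for t in starts) if np.isfinite(e)), None)
        if base_err is None:
            raise FitFailureError("every random start produced an unstable network")
        ws.lambda_l1 = cfg.l1_fraction * base_err

    explored = []
    for idx, theta0 in enumerate(starts):
        theta, obj, step, used = _descend(ws, theta0, cfg.explore_iters, cfg.step_init, cfg)
        err = ws.error(theta)
        explored.append((err, idx, theta, obj, step, used))
    finite = [e for e in explored if np.isfinite(e[0])]
    if not finite:
        raise FitFailureError("every gradient-descent start diverged to an unstable network")
    # best residual error; ties broken by the lowest start index
    best = min(finite, key=lambda e: (e[0], e[1]))
    err0, start_index, theta, _, step, used0 = best
    theta, obj, step, used1 = _descend(ws, theta, cfg.refine_iters, step, cfg)

    # -- assemble the fit --------------------------------------------------
    d_arr, db_arr, amps = ws.unpack(theta)
    d_map = {c.pair: float(v) for c, v in zip(model.connections, d_arr)}
    db_map = {c.pair: float(v) for c, v in zip(model.connections, db_arr)}
    matrices = build_matrices(model, d_map, db_map)
    basis = latent_basis(matrices)
    amp_map = {
        model.latents[k].name: float(a) for k, a in zip(ws.fixed_idx, amps)
    }
    latents = solve_latent_timecourses(matrices, basis, fit_data, amp_map, templates)
    s_output, s_input = forward_signals(matrices, basis, latents)

    # All reported quantities refer to the variance-normalized data the
    # model was fitted to; the per-region R^2 values (and their average)
    # are identical in either space, and d_values_original_units() maps D
    # back to raw data units.
    b_map = {pair: db_map[pair] / d_map[pair] for pair in d_map}
    metrics = fit_metrics(s_input, fit_data.data, model.regions)

    convergence = {
        "start_index": int(start_index),
        "explore_iterations": int(used0),
        "refine_iterations": int(used1),
        "final_step": float(step),
        "objective": float(obj),
        "lambda_l1": float(ws.lambda_l1),
        "seed": int(cfg.seed),
        "explore_errors": [float(e[0]) for e in sorted(explored, key=lambda e: e[1])],
    }
    return SAPMFit(
        d_values=d_map,
        db_values=db_map,
        b_values=b_map,
        fixed_latent_amplitudes=amp_map,
        latent_timecourses=latents,
        s_output=s_output,
        s_input=s_input,
        metrics=metrics,
        convergence=convergence,
        regions=list(model.regions),
        latent_names=[l.name for l in model.latents],
        connections=[c.pair for c in model.connections],
        scale_factors=factors,
    )
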