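"""Null-simulation calibration and group-level inference on connections.

Fitting the network to pure Gaussian noise does not yield DB values
centered exactly at zero: the interplay of the modeled connections can
bias individual connections positive or negative even under the null.
Group inference therefore compares each connection's group-mean DB value
against a *null reference* — the distribution of DB values across many
fits to independent Gaussian datasets of the same shape.  T statistics
formed this way follow Student's T, so significance is assessed with a
t-test at a Bonferroni-corrected threshold (family-wise alpha divided by
the number of connections).  D values are positive by construction and
are not significance-tested.

Associations between DB values and behavioral scores (e.g., pain ratings)
use Pearson correlation with Fisher's Z-transform,
``Z = atanh(R) * sqrt(N - 3)``, referred to the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import FitConfig, FitFailureError, SAPMFit, fit_sapm
from .network import NetworkModel, connection_key, network_hash
from .simulate import simulate_null_dataset

__all__ = [
    "NullReference",
    "GroupConnectionStats",
    "BehaviorAssociation",
    "CalibrationError",
    "bonferroni_threshold",
    "build_null_reference",
    "group_connection_test",
    "behavior_association",
    "null_group_tvalue_distribution",
    "group_t_statistics",
    "family_wise_positive_rate",
]


class CalibrationError(Exception):
    """Too many individual null fits failed to build a reference."""


def bonferroni_threshold(alpha: float, n_connections: int) -> float:
    """Uncorrected p-value threshold controlling family-wise error at
    ``alpha`` over ``n_connections`` tests (alpha / n)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_connections < 1:
        raise ValueError("n_connections must be a positive integer")
    return alpha / n_connections


@dataclass
class NullReference:
    """Per-connection DB distributions from fits to Gaussian null data."""

    connections: list[tuple[str, str]]
    db_samples: np.ndarray  # (n_sims, n_connections)
    r2_average: np.ndarray  # (n_sims,)
    r2_total: np.ndarray  # (n_sims,)
    meta: dict = field(default_factory=dict)

    @property
    def n_sims(self) -> int:
        return self.db_samples.shape[0]

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def means(self) -> np.ndarray:
        """The per-connection reference values (null-mean DB)."""
        return self.db_samples.mean(axis=0)

    def sds(self) -> np.ndarray:
        return self.db_samples.std(axis=0, ddof=1)

    def reference_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "connection": [connection_key(*c) for c in self.connections],
                "ref_value": self.means(),
                "ref_sd": self.sds(),
            }
        )


def build_null_reference(
    model: NetworkModel,
    n_sims: int = 100,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    n_runs: int = 5,
    volumes_per_run: int = 40,
    max_failure_fraction: float = 0.05,
) -> NullReference:
    """Fit the model to ``n_sims`` independent Gaussian null datasets.

    Each simulation draws a fresh standard-normal dataset shaped like the
    study design (default 5 runs x 40 volumes) and fits it with the given
    configuration.  Individual fit failures are recorded and re-drawn; if
    more than ``max_failure_fraction`` of attempts fail a
    :class:`CalibrationError` is raised.  Fully reproducible from ``seed``.
    """
    cfg = fit_config or FitConfig()
    rng = np.random.default_rng(seed)
    n_conn = len(model.connections)
    db = np.empty((n_sims, n_conn))
    r2a = np.empty(n_sims)
    r2t = np.empty(n_sims)
    failures = 0
    max_failures = max(1, int(np.ceil(max_failure_fraction * n_sims)))
    done = 0
    while done < n_sims:
        data_seed = int(rng.integers(0, 2**31 - 1))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        data = simulate_null_dataset(
            n_regions=model.n_regions,
            n_runs=n_runs,
            volumes_per_run=volumes_per_run,
            seed=data_seed,
            regions=model.regions,
        )
        try:
            fit = fit_sapm(data, model, _with_seed(cfg, fit_seed))
        except FitFailureError:
            failures += 1
            if failures > max_failures:
                raise CalibrationError(
                    f"{failures} null fits failed (allowed {max_failures} of {n_sims})"
                )
            continue
        db[done] = fit.db_array()
        r2a[done] = fit.metrics.r2_average
        r2t[done] = fit.metrics.r2_total
        done += 1
    return NullReference(
        connections=[c.pair for c in model.connections],
        db_samples=db,
        r2_average=r2a,
        r2_total=r2t,
        meta={
            "network_hash": network_hash(model),
            "n_sims": n_sims,
            "seed": seed,
            "n_runs": n_runs,
            "volumes_per_run": volumes_per_run,
            "n_regions": model.n_regions,
            "failures": failures,
            "fit_config": {
                "n_starts": cfg.n_starts,
                "explore_iters": cfg.explore_iters,
                "refine_iters": cfg.refine_iters,
            },
        },
    )


def _with_seed(cfg: FitConfig, seed: int) -> FitConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


@dataclass
class GroupConnectionStats:
    table: pd.DataFrame  # connection, mean_db, sem, t, p, significant
    n: int
    alpha: float
    threshold: float
    subtract_reference: bool

    def significant_connections(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "connection"])


def group_t_statistics(
    db_matrix: np.ndarray, reference_means: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, sem, T) per connection for a (group x connection) DB matrix.

    ``T = (mean DB - reference) / sem(DB)``; with no reference the group
    mean is tested against zero.
    """
    db_matrix = np.asarray(db_matrix, dtype=float)
    n = db_matrix.shape[0]
    if n < 2:
        raise ValueError("group statistics require at least 2 fits")
    mean = db_matrix.mean(axis=0)
    sem = db_matrix.std(axis=0, ddof=1) / np.sqrt(n)
    ref = np.zeros_like(mean) if reference_means is None else np.asarray(reference_means)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sem > 0, (mean - ref) / sem, 0.0)
    return mean, sem, t


def _db_matrix_from_fits(
    fits: Sequence[SAPMFit], connections: list[tuple[str, str]]
) -> np.ndarray:
    rows = []
    for fit in fits:
        if list(fit.connections) != list(connections):
            raise ValueError(
                "fit connection list does not match the null reference / group "
                "(are these fits from the same network?)"
            )
        rows.append([fit.db_values[c] for c in connections])
    return np.asarray(rows)


def group_connection_test(
    fits: Sequence[SAPMFit],
    null_ref: NullReference,
    alpha: float = 0.05,
    subtract_reference: bool = True,
) -> GroupConnectionStats:
    """Per-connection group t-test of DB values against the null reference.

    Two-tailed p-values use Student's T with N-1 degrees of freedom; the
    significance flag applies the Bonferroni-corrected threshold
    ``alpha / n_connections``.  With ``subtract_reference=False`` the group
    means are tested against zero instead of the null-reference means.
    """
    db = _db_matrix_from_fits(fits, null_ref.connections)
    ref = null_ref.means() if subtract_reference else None
    mean, sem, t = group_t_statistics(db, ref)
    n = db.shape[0]
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    threshold = bonferroni_threshold(alpha, null_ref.n_connections)
    table = pd.DataFrame(
        {
            "connection": [connection_key(*c) for c in null_ref.connections],
            "mean_db": mean,
            "sem": sem,
            "ref_value": null_ref.means() if subtract_reference else 0.0,
            "t": t,
            "p": p,
            "significant": p < threshold,
        }
    )
    return GroupConnectionStats(
        table=table, n=n, alpha=alpha, threshold=threshold, subtract_reference=subtract_reference
    )


@dataclass
class BehaviorAssociation:
    table: pd.DataFrame  # connection, r, z, p, significant
    n: int
    alpha: float
    threshold: float


def behavior_association(
    fits: Sequence[SAPMFit],
    scores: Sequence[float],
    alpha: float = 0.05,
) -> BehaviorAssociation:
    """Correlate per-participant DB values with a behavioral score.

    Pearson R per connection, Fisher-transformed to
    ``Z = atanh(R) sqrt(N - 3)`` and referred to the standard normal
    (two-tailed); the family-wise flag uses the Bonferroni threshold over
    connections.  Requires N >= 4 and non-constant scores.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n != len(fits):
        raise ValueError("scores must align one-to-one with fits")
    if n < 4:
        raise ValueError("the Fisher transform requires at least N = 4 participants")
    if np.std(scores) == 0:
        raise ValueError("behavioral scores are constant; association undefined")
    connections = list(fits[0].connections)
    db = _db_matrix_from_fits(fits, connections)
    centered = db - db.mean(axis=0)
    s_centered = scores - scores.mean()
    denom = np.sqrt(np.sum(centered**2, axis=0) * np.sum(s_centered**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, centered.T @ s_centered / denom, 0.0)
    r = np.clip(r, -0.999999999, 0.999999999)
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = 2.0 * sps.norm.sf(np.abs(z))
    threshold = bonferroni_threshold(alpha, len(connections))
    table = pd.DataFrame(
        {
            "connection": [connection_key(*c) for c in connections],
            "r": r,
            "z": z,
            "p": p,
            "significant": p < threshold,
        }
    )
    return BehaviorAssociation(table=table, n=n, alpha=alpha, threshold=threshold)


def null_group_tvalue_distribution(
    null_ref: NullReference,
    group_size: int,
    n_groups: int,
    seed: int = 0,
    subtract_reference: bool = True,
    finite_pool_correction: bool = False,
) -> np.ndarray:
    """T values for resampled null participant groups.

    Each group draws ``group_size`` null fits from the reference pool
    without replacement (with replacement across groups) and computes the
    per-connection T statistic.  Returns (n_groups, n_connections).

    When the pool is not much larger than the groups, a group's mean is
    correlated with the pool mean it is compared against, deflating the T
    values by about ``sqrt(1 - group_size / pool_size)``.
    ``finite_pool_correction`` divides this factor back out, which is
    appropriate for distributional checks; the uncorrected values match
    the literal resampling procedure and are conservative for
    significance counting.
    """
    if group_size > null_ref.n_sims:
        raise ValueError(
            f"group_size {group_size} exceeds the {null_ref.n_sims} stored null fits"
        )
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    rng = np.random.default_rng(seed)
    ref = null_ref.means() if subtract_reference else None
    out = np.empty((n_groups, null_ref.n_connections))
    for g in range(n_groups):
        idx = rng.choice(null_ref.n_sims, size=group_size, replace=False)
        _, _, t = group_t_statistics(null_ref.db_samples[idx], ref)
        out[g] = t
    if finite_pool_correction and subtract_reference:
        out /= np.sqrt(1.0 - group_size / null_ref.n_sims)
    return out


def family_wise_positive_rate(
    tvalues: np.ndarray, group_size: int, alpha: float = 0.05
) -> float:
    """Fraction of groups in which any connection passes the
    Bonferroni-corrected two-tailed t-test."""
    tvalues = np.atleast_2d(tvalues)
    n_connections = tvalues.shape[1]
    p = 2.0 * sps.t.sf(np.abs(tvalues), df=group_size - 1)
    threshold = bonferroni_threshold(alpha, n_connections)
    return float(np.mean(np.any(p < threshold, axis=1)))
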