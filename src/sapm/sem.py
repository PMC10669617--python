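"""Exhaustive two-source structural-equation-model (SEM) scan.

Used to nominate candidate network edges from the data alone: every
region/cluster node is modeled in turn as a target whose time series is
regressed, without intercept, on every pair of nodes from other regions,

    S_target = beta1 * S_source1 + beta2 * S_source2,

one participant at a time.  Group t-tests on the betas (and optionally
their correlation with behavioral scores), Bonferroni-corrected over the
total number of (target, pair, coefficient) tests, flag consistent
influences.  Edges are classified by the analysis window in which they
reach significance: only before stimulation, only during the
stimulation-inclusive window, or both.  The scan proposes edges; it never
modifies a network model automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bonferroni_threshold

__all__ = [
    "DegenerateSourcesError",
    "TwoSourceScanResult",
    "fit_two_source",
    "count_two_source_tests",
    "exhaustive_two_source_scan",
    "write_edges_dot",
]


class DegenerateSourcesError(Exception):
    """The two source series are (near-)collinear."""


def fit_two_source(
    target_ts: np.ndarray,
    source1_ts: np.ndarray,
    source2_ts: np.ndarray,
    cond_limit: float = 1e10,
) -> tuple[float, float]:
    """Ordinary least-squares (no intercept) of the target on two sources.

    The series are mean-removed percent-change, so no intercept is fitted.
    Raises :class:`DegenerateSourcesError` when the source pair is
    collinear beyond ``cond_limit``.
    """
    x = np.column_stack([np.asarray(source1_ts, float), np.asarray(source2_ts, float)])
    y = np.asarray(target_ts, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("target and source series must have equal length")
    if np.linalg.cond(x) > cond_limit:
        raise DegenerateSourcesError("source time series are collinear")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(beta[0]), float(beta[1])


def count_two_source_tests(n_regions: int, clusters_per_region: int) -> int:
    """Number of (target, source pair, coefficient) combinations:
    R*c targets x C((R-1)*c, 2) source pairs x 2 coefficients."""
    n_targets = n_regions * clusters_per_region
    n_sources = (n_regions - 1) * clusters_per_region
    n_pairs = n_sources * (n_sources - 1) // 2
    return n_targets * n_pairs * 2


@dataclass
class TwoSourceScanResult:
    results: pd.DataFrame
    edges: pd.DataFrame  # from, to, window_class, t, p
    n_tests: int
    threshold: float
    skipped_pairs: list = field(default_factory=list)

    def significant(self, window: str | None = None) -> pd.DataFrame:
        mask = self.results["significant"]
        if window is not None:
            mask = mask & (self.results["window"] == window)
        return self.results.loc[mask]


def _node_name(region: str, cluster: int) -> str:
    return f"{region}[{cluster}]"


def exhaustive_two_source_scan(
    participant_data: Sequence[Mapping[str, np.ndarray]],
    windows: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    scores: Sequence[float] | None = None,
) -> TwoSourceScanResult:
    """Fit every (target, source-pair) combination per participant per window.

    ``participant_data`` maps, per participant, region name -> (k x T)
    cluster time courses; ``windows`` maps a label (e.g. ``"pre"``,
    ``"stim"``) to a boolean mask over the concatenated time axis.  Group
    T statistics test each mean beta against zero; the Bonferroni
    denominator is the emitted test count per window family.  When
    ``scores`` are given, per-connection correlations of beta with the
    score are Fisher-transformed and reported alongside.
    """
    if not participant_data:
        raise ValueError("no participant data supplied")
    regions = list(participant_data[0].keys())
    t_len = next(iter(participant_data[0].values())).shape[1]
    for label, mask in windows.items():
        mask = np.asarray(mask)
        if mask.dtype != bool or mask.size != t_len:
            raise ValueError(
                f"window {label!r} must be a boolean mask over the {t_len}-volume axis"
            )
        if not mask.any():
            raise ValueError(f"window {label!r} selects no volumes")

    nodes = [
        (region, cluster)
        for region in regions
        for cluster in range(participant_data[0][region].shape[0])
    ]
    n_part = len(participant_data)

    records = []
    skipped = []
    combos = []
    for target in nodes:
        pool = [n for n in nodes if n[0] != target[0]]
        for s1, s2 in combinations(pool, 2):
            combos.append((target, s1, s2))
    n_tests = len(combos) * 2
    threshold = bonferroni_threshold(alpha, n_tests)

    use_scores = scores is not None
    if use_scores:
        scores = np.asarray(scores, dtype=float)
        if scores.size != n_part:
            raise ValueError("scores must align with participants")

    for label, mask in windows.items():
        mask = np.asarray(mask, dtype=bool)
        for target, s1, s2 in combos:
            betas = np.empty((n_part, 2))
            ok = True
            for i, pdata in enumerate(participant_data):
                y = pdata[target[0]][target[1]][mask]
                x1 = pdata[s1[0]][s1[1]][mask]
                x2 = pdata[s2[0]][s2[1]][mask]
                try:
                    betas[i] = fit_two_source(y, x1, x2)
                except DegenerateSourcesError:
                    skipped.append({"window": label, "target": target, "pair": (s1, s2)})
                    ok = False
                    break
            if not ok:
                continue
            mean = betas.mean(axis=0)
            sem = betas.std(axis=0, ddof=1) / np.sqrt(n_part)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(sem > 0, mean / sem, 0.0)
            p = 2.0 * sps.t.sf(np.abs(t), df=n_part - 1)
            for ci, source in enumerate((s1, s2)):
                rec = {
                    "window": label,
                    "target": _node_name(*target),
                    "source1": _node_name(*s1),
                    "source2": _node_name(*s2),
                    "source": _node_name(*source),
                    "coefficient": ci + 1,
                    "mean_beta": mean[ci],
                    "sem": sem[ci],
                    "t": t[ci],
                    "p": p[ci],
                    "significant": bool(p[ci] < threshold),
                }
                if use_scores and n_part >= 4 and np.std(scores) > 0:
                    r = _pearson(betas[:, ci], scores)
                    z = np.arctanh(np.clip(r, -0.999999999, 0.999999999)) * np.sqrt(n_part - 3)
                    rec["score_r"] = r
                    rec["score_z"] = z
                    rec["score_p"] = 2.0 * sps.norm.sf(abs(z))
                records.append(rec)

    results = pd.DataFrame.from_records(records)
    edges = _classify_edges(results, windows)
    return TwoSourceScanResult(
        results=results,
        edges=edges,
        n_tests=n_tests,
        threshold=threshold,
        skipped_pairs=skipped,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return float(a @ b / denom) if denom > 0 else 0.0


def _classify_edges(results: pd.DataFrame, windows: Mapping) -> pd.DataFrame:
    """Collapse significant coefficients into directed edges labeled by the
    window(s) in which they are significant."""
    if results.empty:
        return pd.DataFrame(columns=["from", "to", "window_class", "t", "p"])
    sig = results.loc[results["significant"]]
    labels = list(windows.keys())
    rows = []
    for (src, tgt), grp in sig.groupby(["source", "target"]):
        present = set(grp["window"])
        if len(labels) >= 2 and set(labels[:2]) <= present:
            cls = "both"
        elif labels and labels[0] in present and len(present) == 1:
            cls = labels[0]
        elif len(labels) >= 2 and labels[1] in present and len(present) == 1:
            cls = labels[1]
        else:
            cls = "+".join(sorted(present))
        strongest = grp.loc[grp["p"].idxmin()]
        rows.append(
            {"from": src, "to": tgt, "window_class": cls, "t": strongest["t"], "p": strongest["p"]}
        )
    return pd.DataFrame(rows, columns=["from", "to", "window_class", "t", "p"])


def write_edges_dot(edges: pd.DataFrame, path: str | Path) -> None:
    """Emit the significant-edge graph as a simple DOT file."""
    colors = {"both": "black", "pre": "red", "stim": "blue"}
    lines = ["digraph two_source_sem {"]
    for _, row in edges.iterrows():
        color = colors.get(row["window_class"], "gray")
        lines.append(
            f'  "{row["from"]}" -> "{row["to"]}" '
            f'[color={color}, label="{row["window_class"]}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
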