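"""File formats: time-series tables, fit results, null references, stats.

Time-series tables are long-format CSV with columns (participant, run,
volume, region, value) and ``#``-prefixed header lines declaring the
format version, units, and TR.  Volume indices are 0-based within each
run; runs concatenate in ascending run order.  Fit results and null
references round-trip through JSON (+ CSV for per-simulation samples);
stats tables are TSV with a fixed, documented column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import BoldDataset, FitMetrics, SAPMFit
from .network import NetworkModel, connection_key
from .stats import BehaviorAssociation, GroupConnectionStats, NullReference
from .subregions import SubRegionMap, SubRegionSelection

__all__ = [
    "percent_signal_change",
    "write_timeseries_table",
    "read_timeseries_table",
    "write_fit",
    "read_fit",
    "write_null_reference",
    "read_null_reference",
    "write_stats_table",
    "write_subregion_map",
    "write_selection",
    "write_results",
]

FORMAT_VERSION = "sapm/1"

STATS_COLUMNS = ["connection", "mean_db", "sem", "ref_value", "t", "p", "significant"]
ASSOC_COLUMNS = ["connection", "r", "z", "p", "significant"]


def percent_signal_change(values: np.ndarray, regions: Sequence[str] | None = None) -> np.ndarray:
    """Convert raw series to percent change from each region's mean:
    ``100 * (x - mean) / mean`` over the full concatenated series.

    Raises when a region's mean is zero (conversion undefined).
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    means = x.mean(axis=1)
    zero = np.nonzero(means == 0)[0]
    if zero.size:
        names = (
            ", ".join(regions[i] for i in zero)
            if regions is not None
            else ", ".join(str(i) for i in zero)
        )
        raise ValueError(f"zero-mean region(s), percent change undefined: {names}")
    return 100.0 * (x - means[:, None]) / means[:, None]


# ---------------------------------------------------------------------------
# Time-series tables
# ---------------------------------------------------------------------------


def write_timeseries_table(
    datasets: Sequence[BoldDataset],
    path: str | Path,
    tr: float = 6.75,
    units: str = "percent",
) -> None:
    frames = []
    for i, ds in enumerate(datasets):
        pid = ds.participant or f"p{i:03d}"
        for run_idx, (start, length) in enumerate(ds.runs):
            block = ds.data[:, start : start + length]
            for ri, region in enumerate(ds.regions):
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": pid,
                            "run": run_idx,
                            "volume": np.arange(length),
                            "region": region,
                            "value": block[ri],
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# format: {FORMAT_VERSION} timeseries\n")
        fh.write(f"# tr_s: {tr}\n")
        fh.write(f"# units: {units}\n")
        table.to_csv(fh, index=False)


def read_timeseries_table(path: str | Path, model: NetworkModel) -> list[BoldDataset]:
    """Load per-participant datasets, validated against a network model.

    Checks that exactly the model's regions are present, that volume
    indices are contiguous within each run, and that runs are consistent
    across regions; raises structured errors naming the offender.
    """
    path = Path(path)
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"participant", "run", "volume", "region", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"{path.name}: missing column(s) {sorted(missing_cols)}")
    if not np.issubdtype(table["value"].dtype, np.number):
        bad = table.loc[pd.to_numeric(table["value"], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(f"{path.name}: non-numeric value near row {row}")

    file_regions = set(table["region"].unique())
    model_regions = set(model.regions)
    unknown = file_regions - model_regions
    if unknown:
        raise ValueError(f"{path.name}: region(s) not in the model: {sorted(unknown)}")
    absent = model_regions - file_regions
    if absent:
        raise ValueError(f"{path.name}: model region(s) missing from file: {sorted(absent)}")

    datasets = []
    for pid, sub in table.groupby("participant", sort=True):
        runs: list[tuple[int, int]] = []
        blocks = []
        run_ids = sorted(sub["run"].unique())
        offset = 0
        for run_id in run_ids:
            run_tab = sub.loc[sub["run"] == run_id]
            lengths = run_tab.groupby("region")["volume"].agg(["min", "max", "count"])
            if lengths["count"].nunique() != 1 or lengths["min"].nunique() != 1:
                raise ValueError(
                    f"{path.name}: participant {pid} run {run_id}: ragged run "
                    "(regions disagree on volume count)"
                )
            n_vol = int(lengths["count"].iloc[0])
            vols = np.sort(run_tab["volume"].unique())
            if not np.array_equal(vols, np.arange(n_vol)):
                raise ValueError(
                    f"{path.name}: participant {pid} run {run_id}: volume indices "
                    "are not contiguous from 0"
                )
            wide = run_tab.pivot_table(index="region", columns="volume", values="value")
            blocks.append(wide.reindex(model.regions).to_numpy())
            runs.append((offset, n_vol))
            offset += n_vol
        datasets.append(
            BoldDataset(
                data=np.concatenate(blocks, axis=1),
                runs=runs,
                regions=list(model.regions),
                participant=str(pid),
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


def write_fit(fit: SAPMFit, path: str | Path, timecourses: bool = True) -> None:
    """Serialize a fit to JSON (parameter maps keyed "source->target");
    latent/signal time courses go to a sibling CSV unless disabled."""
    path = Path(path)
    doc = {
        "format": f"{FORMAT_VERSION} fit",
        "regions": fit.regions,
        "latent_names": fit.latent_names,
        "connections": [connection_key(*c) for c in fit.connections],
        "d_values": {connection_key(*c): fit.d_values[c] for c in fit.connections},
        "db_values": {connection_key(*c): fit.db_values[c] for c in fit.connections},
        "b_values": {connection_key(*c): fit.b_values[c] for c in fit.connections},
        "fixed_latent_amplitudes": fit.fixed_latent_amplitudes,
        "metrics": fit.metrics.to_dict(),
        "convergence": fit.convergence,
        "scale_factors": fit.scale_factors,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    if timecourses:
        tc_path = path.with_suffix(".timecourses.csv")
        frames = {}
        for i, name in enumerate(fit.latent_names):
            frames[f"L:{name}"] = fit.latent_timecourses[i]
        nodes = fit.regions + fit.latent_names
        for i, name in enumerate(nodes):
            frames[f"S_output:{name}"] = fit.s_output[i]
        for i, name in enumerate(fit.regions):
            frames[f"S_input:{name}"] = fit.s_input[i]
        pd.DataFrame(frames).to_csv(tc_path, index_label="volume")


def read_fit(path: str | Path) -> SAPMFit:
    doc = json.loads(Path(path).read_text())
    pairs = [tuple(k.split("->", 1)) for k in doc["connections"]]
    tc_path = Path(path).with_suffix(".timecourses.csv")
    if tc_path.exists():
        tc = pd.read_csv(tc_path, index_col="volume", float_precision="round_trip")
        latent = np.vstack([tc[f"L:{n}"].to_numpy() for n in doc["latent_names"]])
        nodes = doc["regions"] + doc["latent_names"]
        s_out = np.vstack([tc[f"S_output:{n}"].to_numpy() for n in nodes])
        s_in = np.vstack([tc[f"S_input:{n}"].to_numpy() for n in doc["regions"]])
    else:
        latent = s_out = s_in = np.zeros((0, 0))
    m = doc["metrics"]
    return SAPMFit(
        d_values={p: doc["d_values"][connection_key(*p)] for p in pairs},
        db_values={p: doc["db_values"][connection_key(*p)] for p in pairs},
        b_values={p: doc["b_values"][connection_key(*p)] for p in pairs},
        fixed_latent_amplitudes=dict(doc["fixed_latent_amplitudes"]),
        latent_timecourses=latent,
        s_output=s_out,
        s_input=s_in,
        metrics=FitMetrics(
            err_ssqd=m["err_ssqd"],
            r2_total=m["r2_total"],
            r2_average=m["r2_average"],
            r2_per_region=dict(m["r2_per_region"]),
            excluded_regions=list(m["excluded_regions"]),
        ),
        convergence=dict(doc["convergence"]),
        regions=list(doc["regions"]),
        latent_names=list(doc["latent_names"]),
        connections=pairs,
        scale_factors=dict(doc["scale_factors"]),
    )


# ---------------------------------------------------------------------------
# Null reference / stats tables / selections
# ---------------------------------------------------------------------------


def write_null_reference(ref: NullReference, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "format": f"{FORMAT_VERSION} null-reference",
        "connections": [connection_key(*c) for c in ref.connections],
        "meta": ref.meta,
        "r2_average": [float(v) for v in ref.r2_average],
        "r2_total": [float(v) for v in ref.r2_total],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    samples = pd.DataFrame(
        ref.db_samples, columns=[connection_key(*c) for c in ref.connections]
    )
    # full precision so reloaded references reproduce T values bitwise
    samples.to_csv(path.with_suffix(".samples.csv"), index_label="sim", float_format="%.17g")


def read_null_reference(path: str | Path) -> NullReference:
    path = Path(path)
    doc = json.loads(path.read_text())
    samples = pd.read_csv(
        path.with_suffix(".samples.csv"), index_col="sim", float_precision="round_trip"
    )
    connections = [tuple(k.split("->", 1)) for k in doc["connections"]]
    return NullReference(
        connections=connections,
        # C-contiguous so reductions reproduce the original bitwise
        db_samples=np.ascontiguousarray(samples.to_numpy()),
        r2_average=np.asarray(doc["r2_average"]),
        r2_total=np.asarray(doc["r2_total"]),
        meta=dict(doc["meta"]),
    )


def write_stats_table(stats, path: str | Path) -> None:
    """Stats tables as TSV.  Column order is fixed: group tests emit
    (connection, mean_db, sem, ref_value, t, p, significant); associations
    emit (connection, r, z, p, significant)."""
    if isinstance(stats, GroupConnectionStats):
        table = stats.table[STATS_COLUMNS]
    elif isinstance(stats, BehaviorAssociation):
        table = stats.table[ASSOC_COLUMNS]
    else:
        table = stats
    table.to_csv(path, sep="\t", index=False)


def write_subregion_map(srmap: SubRegionMap, path: str | Path) -> None:
    records = srmap.to_records()
    pd.DataFrame(records, columns=["region", "voxel", "cluster"]).to_csv(path, index=False)


def write_selection(selection: SubRegionSelection, path: str | Path) -> None:
    doc = {
        "format": f"{FORMAT_VERSION} subregion-selection",
        "selection": selection.selection,
        "r2_average": selection.r2_average,
        "n_sweeps": selection.n_sweeps,
        "trace": selection.trace,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_results(obj, path: str | Path) -> None:
    """Dispatch on object type: fits, null references, stats tables, and
    sub-region selections each go to their canonical on-disk form."""
    if isinstance(obj, SAPMFit):
        write_fit(obj, path)
    elif isinstance(obj, NullReference):
        write_null_reference(obj, path)
    elif isinstance(obj, (GroupConnectionStats, BehaviorAssociation, pd.DataFrame)):
        write_stats_table(obj, path)
    elif isinstance(obj, SubRegionSelection):
        write_selection(obj, path)
    elif isinstance(obj, SubRegionMap):
        write_subregion_map(obj, path)
    else:
        raise TypeError(f"do not know how to write {type(obj).__name__}")
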