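"""Serialisation of calculator and simulation results (CSV / JSON / text)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .errors import InvalidParameterError

__all__ = ["records_to_frame", "write_results", "render_sample_size_report"]

FORMATS = ("csv", "json")


def _as_dict(record: Any) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise InvalidParameterError(
        f"records must be dataclasses or mappings; got {type(record).__name__}"
    )


def records_to_frame(records: Iterable[Any]) -> pd.DataFrame:
    """Normalise a batch of result records to a DataFrame with stable
    column order (first record's field order wins)."""
    dicts = [_as_dict(r) for r in records]
    if not dicts:
        raise InvalidParameterError("records must be non-empty")
    return pd.DataFrame(dicts, columns=list(dicts[0].keys()))


def write_results(records: Iterable[Any] | pd.DataFrame, path: str | Path,
                  fmt: str = "csv") -> Path:
    """Write result records to ``path`` as CSV (header row, one record per
    row) or JSON (array of flat objects).  Re-reading round-trips the
    numeric content."""
    if fmt not in FORMATS:
        raise InvalidParameterError(f"format must be one of {FORMATS}; got {fmt!r}")
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise InvalidParameterError("records must be non-empty")
    path = Path(path)
    try:
        if fmt == "csv":
            frame.to_csv(path, index=False)
        else:
            path.write_text(
                json.dumps(frame.to_dict(orient="records"), indent=2) + "\n"
            )
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return path


def render_sample_size_report(result, cluster=None, inflated=None) -> str:
    """Human-readable report for one sample-size calculation."""
    from .samplesize import design_effect  # local import avoids a cycle

    lines = [
        "Sample size for a two-group comparison of medians",
        f"  method:               {result.method_tag}",
        f"  log-median difference tau = {result.tau:.6f}",
        f"  log-scale variances:  sigma1^2 = {result.sigma_sq_1:.6f}, "
        f"sigma2^2 = {result.sigma_sq_2:.6f}",
        f"  continuous n:         {result.n_continuous:.2f}",
        f"  per-group n (rounded up, +{result.small_sample_pad} pad): "
        f"{result.n_per_group}",
    ]
    if result.note:
        lines.append(f"  note: {result.note}")
    if cluster is not None and inflated is not None:
        n_units, n_clusters = inflated
        lines += [
            f"  design effect (ICC {cluster.icc}, cluster size "
            f"{cluster.avg_cluster_size}): {design_effect(cluster):.4g}",
            f"  inflated units per group:    {n_units}",
            f"  clusters per group:          {n_clusters}",
        ]
    return "\n".join(lines)
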