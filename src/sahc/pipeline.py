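"""End-to-end helpers chaining cleaning, epoching and classification."""

from __future__ import annotations

import pandas as pd

from .classify import PssResult, classify_clean_run
from .exceptions import UnclassifiableRunError
from .preprocess import clean_run, run_epoch_table
from .records import RunRecord


def process_runs(
    runs: list[RunRecord],
    limits: dict | None = None,
    max_sd_multiple: float = 3.0,
    rate: float = 4.0,
    classify: bool = True,
) -> tuple[pd.DataFrame, list[PssResult], dict[str, dict[str, str]]]:
    """Clean, epoch and (optionally) PSS-classify a collection of runs.

    Returns ``(epoch_table, pss_results, rejected)``.  A channel failing
    the validity gate drops only that channel from that run; a run
    missing HR or MAP is skipped by the classifier and recorded in
    ``rejected`` under the pseudo-channel ``"_classify"``.
    """
    tables = []
    pss: list[PssResult] = []
    rejected: dict[str, dict[str, str]] = {}
    for run in runs:
        clean, rej = clean_run(run, limits=limits, max_sd_multiple=max_sd_multiple, rate=rate)
        if rej:
            rejected.setdefault(run.run_id, {}).update(rej)
        tables.append(run_epoch_table(run, clean))
        if classify:
            try:
                pss.append(classify_clean_run(run, clean))
            except UnclassifiableRunError as exc:
                rejected.setdefault(run.run_id, {})["_classify"] = str(exc)
    tables = [t for t in tables if not t.empty]
    epoch_table = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    return epoch_table, pss, rejected


def pss_counts_by_position(pss: list[PssResult], runs: list[RunRecord]) -> pd.DataFrame:
    """PSS+/PSS- contingency counts by rotation-axis position."""
    pos_of = {r.run_id: r.position for r in runs}
    rows = {}
    for res in pss:
        pos = pos_of[res.run_id]
        rows.setdefault(pos, {"PSS+": 0, "PSS-": 0})
        rows[pos][res.label] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return table.sort_index()[["PSS+", "PSS-"]]
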