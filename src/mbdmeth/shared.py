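"""Cross-patient sharing of aberrantly methylated regions.

All patients are tested on one merged region universe, so sharing is
defined by region identity, not positional re-intersection.  Sharing is
direction-stratified: a hypomethylated and a hypermethylated call at the
same region never pool.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .diffmeth import HYPER, HYPO
from .intervals import GenomicInterval

_KEY = ["chrom", "start", "end"]


def build_shared(
    per_patient_calls: Mapping[str, pd.DataFrame],
    universe: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Aggregate per-patient differential tables into shared-region rows.

    ``per_patient_calls`` maps patient id to a frame with chrom/start/end
    and direction columns (rows with direction ``none`` are ignored).
    Returns one row per (region, direction) with the affected patient set.
    """
    universe_keys = {(r.chrom, r.start, r.end) for r in universe}
    records: dict[tuple, set[str]] = {}
    for patient, df in per_patient_calls.items():
        called = df[df["direction"].isin([HYPO, HYPER])]
        for chrom, start, end, direction in zip(
            called["chrom"], called["start"], called["end"], called["direction"]
        ):
            key = (chrom, int(start), int(end))
            if key not in universe_keys:
                raise KeyError(f"region {key} not in the merged universe")
            records.setdefault(key + (direction,), set()).add(patient)
    rows = [
        {"chrom": c, "start": s, "end": e, "direction": d,
         "patients": frozenset(pats), "n_patients": len(pats)}
        for (c, s, e, d), pats in records.items()
    ]
    df = pd.DataFrame(rows, columns=_KEY + ["direction", "patients", "n_patients"])
    return df.sort_values(_KEY + ["direction"], ignore_index=True)


def venn_counts(report: pd.DataFrame, patients: Sequence[str]
                ) -> pd.DataFrame:
    """Exact Venn partition: each (region, direction) contributes to the one
    cell given by the full set of patients calling it.

    Returns one row per non-empty patient subset with hypo and hyper counts.
    """
    cells: dict[frozenset, list[int]] = {}
    for _, row in report.iterrows():
        cell = cells.setdefault(row["patients"], [0, 0])
        cell[0 if row["direction"] == HYPO else 1] += 1
    order = {p: i for i, p in enumerate(patients)}
    rows = []
    for subset, (h, y) in cells.items():
        members = sorted(subset, key=lambda p: order.get(p, len(order)))
        rows.append({"subset": ",".join(members), "size": len(subset),
                     "hypo": h, "hyper": y})
    df = pd.DataFrame(rows, columns=["subset", "size", "hypo", "hyper"])
    return df.sort_values(["size", "subset"], ignore_index=True)


def shared_at_least(report: pd.DataFrame, k: int = 2
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regions aberrant in at least ``k`` patients, split by direction.

    Each frame is sorted by descending patient count, then coordinate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sel = report[report["n_patients"] >= k]
    out = []
    for direction in (HYPO, HYPER):
        sub = sel[sel["direction"] == direction].sort_values(
            ["n_patients"] + _KEY, ascending=[False, True, True, True],
            ignore_index=True,
        )
        out.append(sub)
    return out[0], out[1]
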