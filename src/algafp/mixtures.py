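"""Peak attribution across constituent and mixture spectra.

Every distinct peak (clustered at the match tolerance across all lists)
is labeled:

* ``M`` — constituent-derived and observed in at least one mixture
* ``P`` — constituent-derived but observed in no mixture (suppressed)
* ``S`` — mixture-specific (matches no constituent peak)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import (
    ConsensusPeakList,
    DEFAULT_TOLERANCE,
    MatchTolerance,
    consensus_lists_from_table,
)


def load_packaged_mixture_example() -> tuple[list[ConsensusPeakList], list[ConsensusPeakList]]:
    """Load the packaged two/three-algae mixture example (constituent and
    mixture consensus peak lists)."""
    from importlib.resources import files

    from .io_formats import read_peak_table

    data = files("algafp") / "data"
    constituents = consensus_lists_from_table(
        read_peak_table(str(data / "mixture_example_constituents.tsv"))
    )
    mixtures = consensus_lists_from_table(
        read_peak_table(str(data / "mixture_example_mixtures.tsv"))
    )
    return constituents, mixtures


@dataclass
class MixturePeakTable:
    """Per-peak presence flags and M/P/S labels.

    ``table`` columns: mz, one column per constituent and per mixture
    holding "M"/"P"/"S"/"" cell labels, plus a global ``label`` column.
    """

    table: pd.DataFrame
    constituent_ids: list[str]
    mixture_ids: list[str]

    def labels(self) -> pd.Series:
        return self.table.set_index("mz")["label"]


def _cluster_union_peaks(
    lists: dict[str, np.ndarray], tol: float
) -> list[tuple[float, set[str]]]:
    """Single-linkage chaining of all peaks at tolerance ``tol``.

    Returns (cluster centroid m/z, set of sample ids present) per cluster.
    """
    entries = sorted(
        (float(mz), sid) for sid, mzs in lists.items() for mz in mzs
    )
    clusters: list[tuple[float, set[str]]] = []
    current: list[tuple[float, str]] = []
    for mz, sid in entries:
        if current and mz - current[-1][0] > tol:
            clusters.append(
                (float(np.mean([m for m, _ in current])), {s for _, s in current})
            )
            current = []
        current.append((mz, sid))
    if current:
        clusters.append(
            (float(np.mean([m for m, _ in current])), {s for _, s in current})
        )
    return clusters


def classify_mixture_peaks(
    constituents: list[ConsensusPeakList],
    mixtures: list[ConsensusPeakList],
    t: MatchTolerance | float = DEFAULT_TOLERANCE,
) -> MixturePeakTable:
    """Label every union peak M, P, or S (see module docstring)."""
    if not constituents:
        raise ValueError("need at least one constituent peak list")
    if not mixtures:
        raise ValueError("need at least one mixture peak list")
    tol = t.tol if isinstance(t, MatchTolerance) else float(t)
    constituent_ids = [c.sample_id for c in constituents]
    mixture_ids = [m.sample_id for m in mixtures]
    if len(set(constituent_ids + mixture_ids)) != len(constituent_ids) + len(mixture_ids):
        raise ValueError("sample ids must be unique across constituents and mixtures")
    lists = {c.sample_id: c.mzs for c in constituents}
    lists.update({m.sample_id: m.mzs for m in mixtures})
    clusters = _cluster_union_peaks(lists, tol)
    rows = []
    for mz, present in clusters:
        in_constituent = any(cid in present for cid in constituent_ids)
        in_mixture = any(mid in present for mid in mixture_ids)
        if in_constituent and in_mixture:
            label = "M"
        elif in_constituent:
            label = "P"
        else:
            label = "S"
        row: dict[str, object] = {"mz": round(mz, 4)}
        for cid in constituent_ids:
            row[cid] = label if (cid in present and label in ("M", "P")) else ""
        for mid in mixture_ids:
            if mid in present:
                row[mid] = "M" if label == "M" else "S"
            else:
                row[mid] = ""
        row["label"] = label
        rows.append(row)
    table = pd.DataFrame(rows, columns=["mz", *constituent_ids, *mixture_ids, "label"])
    return MixturePeakTable(
        table=table, constituent_ids=constituent_ids, mixture_ids=mixture_ids
    )


def mixture_specific_peaks(table: MixturePeakTable) -> list[float]:
    """m/z of the S-labeled (mixture-only) peaks, sorted ascending."""
    mzs = table.table.loc[table.table["label"] == "S", "mz"]
    return sorted(float(m) for m in mzs)


def suppression_report(table: MixturePeakTable) -> pd.DataFrame:
    """Per-constituent counts of peaks observed in any mixture (M) vs
    suppressed (P), with the suppressed fraction."""
    rows = []
    for cid in table.constituent_ids:
        col = table.table[cid]
        n_obs = int((col == "M").sum())
        n_sup = int((col == "P").sum())
        total = n_obs + n_sup
        rows.append(
            {
                "sample_id": cid,
                "n_observed": n_obs,
                "n_suppressed": n_sup,
                "suppressed_fraction": (n_sup / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
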