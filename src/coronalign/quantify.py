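"""Per-region quantification: pixel proportions, cell counts, ontology roll-up.

The warped atlas annotation assigns a region id to every tissue pixel.  Two
integrations are supported: the proportion of binary-signal pixels (e.g.
thresholded ISH signal) per region, and counts of detected cells assigned to
the region under each detection's box centre.  A region ontology (id,
acronym, name, parent id) supports rolling leaf counts up to coarser
anatomical levels; totals are preserved exactly (integer arithmetic).

Detections whose centre lands on background (label 0) are reported under the
reserved "unassigned" row (region id 0), never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Detection

UNASSIGNED_ID = 0
UNASSIGNED_ACRONYM = "unassigned"

REGION_TABLE_COLUMNS = [
    "region_id", "acronym", "total_px", "signal_px", "proportion", "cell_count",
]


@dataclass
class Ontology:
    """Region ontology: unique ids, acyclic parent links, at least one root."""

    table: pd.DataFrame  # columns: id, acronym, name, parent_id (NaN for roots)

    def __post_init__(self) -> None:
        required = {"id", "acronym", "parent_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ontology missing columns: {sorted(missing)}")
        if "name" not in self.table.columns:
            self.table = self.table.assign(name=self.table["acronym"])
        if self.table["id"].duplicated().any():
            raise ValueError("ontology ids must be unique")
        self._parent = dict(zip(self.table["id"], self.table["parent_id"]))
        roots = [i for i, p in self._parent.items() if pd.isna(p)]
        if not roots:
            raise ValueError("ontology must contain at least one root")
        self._check_acyclic()
        self._by_acronym = dict(zip(self.table["acronym"], self.table["id"]))

    def _check_acyclic(self) -> None:
        for start in self._parent:
            seen = set()
            node = start
            while node in self._parent and not pd.isna(self._parent[node]):
                if node in seen:
                    raise ValueError(f"ontology parent links contain a cycle at id {node}")
                seen.add(node)
                node = self._parent[node]

    @classmethod
    def from_csv(cls, path) -> "Ontology":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def acronym_of(self, region_id: int) -> str:
        if region_id == UNASSIGNED_ID:
            return UNASSIGNED_ACRONYM
        row = self.table.loc[self.table["id"] == region_id, "acronym"]
        return str(row.iloc[0]) if len(row) else str(region_id)

    def id_of(self, acronym: str) -> int:
        if acronym == UNASSIGNED_ACRONYM:
            return UNASSIGNED_ID
        if acronym not in self._by_acronym:
            raise KeyError(f"unknown acronym {acronym!r}")
        return int(self._by_acronym[acronym])

    def ancestors(self, region_id: int):
        """Yield region_id, then each parent up to the root."""
        node = region_id
        while True:
            yield int(node)
            p = self._parent.get(node, np.nan)
            if pd.isna(p):
                return
            node = int(p)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=REGION_TABLE_COLUMNS).astype(
        {"region_id": int, "total_px": int, "signal_px": int,
         "proportion": float, "cell_count": int, "acronym": str}
    )


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["proportion"] = np.where(
        df["total_px"] > 0, df["signal_px"] / df["total_px"].replace(0, 1), 0.0
    )
    return df[REGION_TABLE_COLUMNS].sort_values("region_id").reset_index(drop=True)


def count_pixels_by_region(
    mask: np.ndarray, labels: np.ndarray, ontology: Ontology | None = None
) -> pd.DataFrame:
    """Tally signal-mask pixels per annotated region.

    One row per region id present in the label image (including id 0, the
    off-tissue background, reported as "unassigned"), with total pixel count,
    signal-positive pixel count and their ratio; regions with zero signal are
    still listed.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if mask.shape != labels.shape:
        raise ValueError(f"mask shape {mask.shape} != labels shape {labels.shape}")
    ids = np.unique(labels)
    flat = labels.ravel()
    max_id = int(ids.max()) if ids.size else 0
    total = np.bincount(flat, minlength=max_id + 1)
    signal = np.bincount(flat, weights=mask.ravel().astype(np.int64),
                         minlength=max_id + 1).astype(np.int64)
    rows = [
        {
            "region_id": int(rid),
            "acronym": ontology.acronym_of(int(rid)) if ontology else
            (UNASSIGNED_ACRONYM if rid == UNASSIGNED_ID else str(int(rid))),
            "total_px": int(total[rid]),
            "signal_px": int(signal[rid]),
            "cell_count": 0,
        }
        for rid in ids
    ]
    return _finalize(pd.DataFrame(rows)) if rows else _empty_table()


def assign_detections_to_regions(
    detections: list[Detection],
    labels: np.ndarray,
    ontology: Ontology | None = None,
) -> pd.DataFrame:
    """Count detections per region by the label under each box centre.

    Box centres are clipped into the label image first; a centre on label 0
    is counted under "unassigned".
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    counts: dict[int, int] = {}
    for det in detections:
        cx, cy = det.center
        col = int(np.clip(round(cx), 0, w - 1))
        row = int(np.clip(round(cy), 0, h - 1))
        rid = int(labels[row, col])
        counts[rid] = counts.get(rid, 0) + 1
    ids = sorted(set(np.unique(labels).tolist()) | set(counts))
    rows = [
        {
            "region_id": int(rid),
            "acronym": ontology.acronym_of(int(rid)) if ontology else
            (UNASSIGNED_ACRONYM if rid == UNASSIGNED_ID else str(int(rid))),
            "total_px": int((labels == rid).sum()),
            "signal_px": 0,
            "cell_count": counts.get(rid, 0),
        }
        for rid in ids
    ]
    return _finalize(pd.DataFrame(rows)) if rows else _empty_table()


def merge_region_tables(pixel_table: pd.DataFrame, cell_table: pd.DataFrame) -> pd.DataFrame:
    """Combine a pixel-proportion table and a cell-count table on region id."""
    merged = pixel_table.set_index("region_id").copy()
    cells = cell_table.set_index("region_id")["cell_count"]
    merged["cell_count"] = cells.reindex(merged.index, fill_value=0).astype(int)
    extra = cells.index.difference(merged.index)
    for rid in extra:
        merged.loc[rid] = {
            "acronym": cell_table.set_index("region_id").loc[rid, "acronym"],
            "total_px": 0, "signal_px": 0, "proportion": 0.0,
            "cell_count": int(cells.loc[rid]),
        }
    return _finalize(merged.reset_index())


def rollup(
    table: pd.DataFrame, ontology: Ontology, level: list[str] | set[str]
) -> pd.DataFrame:
    """Aggregate a region table up to a set of target acronyms.

    Each row is attributed to its *nearest* ancestor among the targets (a
    region contributes to exactly one target); rows with no target ancestor
    — including "unassigned" — keep their own identity.  Integer columns sum
    exactly, so totals are conserved.
    """
    targets = {ontology.id_of(a) for a in level}
    out: dict[int, dict] = {}
    for _, row in table.iterrows():
        rid = int(row["region_id"])
        dest = rid
        if rid != UNASSIGNED_ID:
            for anc in ontology.ancestors(rid):
                if anc in targets:
                    dest = anc
                    break
        acc = out.setdefault(
            dest,
            {"region_id": dest, "acronym": ontology.acronym_of(dest),
             "total_px": 0, "signal_px": 0, "cell_count": 0},
        )
        acc["total_px"] += int(row["total_px"])
        acc["signal_px"] += int(row["signal_px"])
        acc["cell_count"] += int(row["cell_count"])
    return _finalize(pd.DataFrame(list(out.values())))
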