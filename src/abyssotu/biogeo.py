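"""Occupancy and region-sharing summaries of the OTU x sample table.

Presence is read count >= 1.  Occupancy classes partition OTUs (and their
reads) by the number of samples they occur in; region sharing splits OTUs
into those found in both regions versus a single region, either requiring
every sample ("all") or at least one sample per region ("min 1").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd


@dataclass
class IncidenceTable:
    """OTU x sample read counts plus a sample -> region map."""

    counts: pd.DataFrame  # index: otu_id, columns: samples
    region_map: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.region_map]
        if missing:
            raise ValueError(f"samples without a region: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def regions(self) -> list[str]:
        # sorted so outputs are invariant under sample reordering
        return sorted({self.region_map[s] for s in self.counts.columns})


def occupancy(table: IncidenceTable) -> pd.DataFrame:
    """OTU and read counts per number-of-samples-occupied class."""
    counts = table.counts
    n_samples = counts.shape[1]
    present = counts > 0
    occ = present.sum(axis=1)
    reads = counts.sum(axis=1)
    rows = []
    for n in range(1, n_samples + 1):
        mask = occ == n
        rows.append(
            {"samples": n, "otus": int(mask.sum()), "reads": int(reads[mask].sum())}
        )
    return pd.DataFrame(rows)


def region_sharing(table: IncidenceTable) -> pd.DataFrame:
    """Bipolar/endemic OTU sets under the 'all samples' and 'min 1 sample' rules.

    Exactly two regions are required.  'all' rows: present in every sample
    of the stated scope and absent from the other region; 'min1' rows:
    present in at least one sample of each stated region.
    """
    regions = table.regions
    if len(regions) != 2:
        raise ValueError(f"region sharing requires exactly 2 regions, got {regions}")
    counts = table.counts
    present = counts > 0
    cols = {r: [s for s in counts.columns if table.region_map[s] == r] for r in regions}
    for r, ss in cols.items():
        if not ss:
            raise ValueError(f"region {r!r} has no samples")
    r1, r2 = regions
    in_all = {r: present[cols[r]].all(axis=1) for r in regions}
    in_any = {r: present[cols[r]].any(axis=1) for r in regions}
    reads = counts.sum(axis=1)

    sets = {
        ("all", f"{r1}+{r2}"): in_all[r1] & in_all[r2],
        ("all", f"{r1} only"): in_all[r1] & ~in_any[r2],
        ("all", f"{r2} only"): in_all[r2] & ~in_any[r1],
        ("min1", f"{r1}+{r2}"): in_any[r1] & in_any[r2],
        ("min1", f"{r1} only"): in_any[r1] & ~in_any[r2],
        ("min1", f"{r2} only"): in_any[r2] & ~in_any[r1],
    }
    rows = []
    for (scope, label), mask in sets.items():
        rows.append(
            {
                "scope": scope,
                "set": label,
                "otus": int(mask.sum()),
                "reads": int(reads[mask].sum()),
                "otu_ids": tuple(counts.index[mask]),
            }
        )
    return pd.DataFrame(rows)


def sharing_taxonomy_profile(
    sharing: pd.DataFrame,
    major_groups: Mapping[str, str],
    plankton_flags: Mapping[str, bool],
    scope: str = "all",
) -> pd.DataFrame:
    """Major-group composition of each sharing set, with percent planktonic
    and percent unassigned.

    ``major_groups`` maps otu_id -> category (including 'Unassigned');
    ``plankton_flags`` maps otu_id -> putative planktonic.
    """
    out: dict[str, dict[str, float]] = {}
    for _, row in sharing[sharing["scope"] == scope].iterrows():
        ids: Sequence[str] = row["otu_ids"]
        col: dict[str, float] = {}
        for otu in ids:
            cat = major_groups.get(otu, "Undetermined")
            col[cat] = col.get(cat, 0) + 1
        n = len(ids)
        col["Total OTUs"] = n
        col["% planktonic"] = (
            round(100.0 * sum(bool(plankton_flags.get(o)) for o in ids) / n, 1)
            if n else 0.0
        )
        col["% unassigned"] = (
            round(
                100.0 * sum(major_groups.get(o) == "Unassigned" for o in ids) / n, 1
            )
            if n else 0.0
        )
        out[row["set"]] = col
    df = pd.DataFrame(out).fillna(0)
    df.index.name = "category"
    return df
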