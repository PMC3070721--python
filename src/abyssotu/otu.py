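"""Strict dereplication and abundance-greedy OTU clustering.

Reads are first collapsed to unique tags (exact string identity) with
per-sample occurrence counts, sorted by decreasing abundance.  Clustering
is a single greedy pass in that order: the most abundant unassigned tag
seeds an OTU and every later unassigned tag within ``k`` counted
differences (homopolymer-insensitive, see :mod:`abyssotu.hpalign`) of that
seed joins it.  Members join the first seed they match; they are never
re-tested against later seeds.

OTUs whose single member was observed exactly once ("single-singletons")
are likely sequencing artifacts; :func:`drop_single_singletons` separates
them, but the pipeline keeps them by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hpalign import _encode, _within_k_kernel, hp_compress
from .seqio import Read


@dataclass
class UniqueTag:
    sequence: str
    abundance: int
    per_sample: dict[str, int]
    rep_id: str

    def __post_init__(self) -> None:
        if self.abundance != sum(self.per_sample.values()) or self.abundance < 1:
            raise ValueError("abundance must equal the sum of per-sample counts")


@dataclass
class OTU:
    seed: UniqueTag
    members: list[UniqueTag]
    k: int

    @property
    def reads(self) -> int:
        return sum(m.abundance for m in self.members)

    @property
    def per_sample_reads(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for m in self.members:
            for s, c in m.per_sample.items():
                out[s] += c
        return dict(out)

    @property
    def is_single_singleton(self) -> bool:
        return len(self.members) == 1 and self.members[0].abundance == 1


def dereplicate(reads: list[Read]) -> list[UniqueTag]:
    """Collapse exactly identical sequences into abundance-counted tags.

    Output is sorted by decreasing abundance, ties broken lexicographically
    by sequence so the pipeline is deterministic.
    """
    counts: dict[str, dict[str, int]] = {}
    first_id: dict[str, str] = {}
    for r in reads:
        per = counts.setdefault(r.sequence, {})
        per[r.sample] = per.get(r.sample, 0) + 1
        first_id.setdefault(r.sequence, r.id)
    tags = [
        UniqueTag(
            sequence=seq,
            abundance=sum(per.values()),
            per_sample=per,
            rep_id=first_id[seq],
        )
        for seq, per in counts.items()
    ]
    tags.sort(key=lambda t: (-t.abundance, t.sequence))
    return tags


def _check_sorted(tags: list[UniqueTag]) -> None:
    for prev, cur in zip(tags, tags[1:]):
        if (-prev.abundance, prev.sequence) > (-cur.abundance, cur.sequence):
            raise ValueError("tags must be sorted by decreasing abundance")


def greedy_cluster(tags: list[UniqueTag], k: int) -> list[OTU]:
    """One greedy pass over abundance-sorted tags.

    Each tag is compared only against existing seeds, most abundant first,
    and joins the first seed within ``k``; otherwise it becomes a new seed.
    Exact identity of homopolymer-compressed forms short-circuits the
    dynamic program (such pairs are at distance 0 by construction).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    _check_sorted(tags)
    otus: list[OTU] = []
    seed_comp: list[str] = []
    seed_enc: list[np.ndarray] = []
    for tag in tags:
        comp = hp_compress(tag.sequence)
        enc = _encode(tag.sequence)
        placed = False
        for idx, otu in enumerate(otus):
            if comp == seed_comp[idx]:
                otu.members.append(tag)
                placed = True
                break
            if k > 0 and _within_k_kernel(seed_enc[idx], enc, k) <= k:
                otu.members.append(tag)
                placed = True
                break
        if not placed:
            otus.append(OTU(seed=tag, members=[tag], k=k))
            seed_comp.append(comp)
            seed_enc.append(enc)
    return otus


def drop_single_singletons(otus: list[OTU]) -> tuple[list[OTU], list[OTU]]:
    """Split off OTUs that are one unique sequence seen exactly once."""
    kept = [o for o in otus if not o.is_single_singleton]
    dropped = [o for o in otus if o.is_single_singleton]
    return kept, dropped


def otu_table(otus: list[OTU], samples: list[str] | None = None) -> pd.DataFrame:
    """OTU summary: id, seed sequence, member/read totals, per-sample reads."""
    if samples is None:
        seen: dict[str, None] = {}
        for o in otus:
            for s in o.per_sample_reads:
                seen.setdefault(s)
        samples = list(seen)
    rows = []
    for i, o in enumerate(otus):
        per = o.per_sample_reads
        row = {
            "otu_id": f"OTU{i + 1:05d}",
            "seed_id": o.seed.rep_id,
            "seed_sequence": o.seed.sequence,
            "n_members": len(o.members),
            "total_reads": o.reads,
        }
        row.update({s: per.get(s, 0) for s in samples})
        rows.append(row)
    cols = ["otu_id", "seed_id", "seed_sequence", "n_members", "total_reads", *samples]
    return pd.DataFrame(rows, columns=cols)


def saturation_curve(
    read_to_otu: dict[str, str] | list[str],
    n_points: int = 20,
    n_perm: int = 100,
    seed: int = 1,
) -> pd.DataFrame:
    """Rarefaction: mean distinct OTUs observed in subsamples of reads.

    Subsampling is without replacement.  Returns a table with columns
    ``reads``, ``mean_otus``, ``sd``; the final point (all reads) equals
    the total OTU count with sd 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = (
        list(read_to_otu.values())
        if isinstance(read_to_otu, dict)
        else list(read_to_otu)
    )
    n = len(labels)
    if n == 0:
        return pd.DataFrame(columns=["reads", "mean_otus", "sd"])
    if n_points > n:
        import warnings

        warnings.warn("n_points exceeds read count; clipping", stacklevel=2)
        n_points = n
    codes = pd.factorize(np.asarray(labels, dtype=object))[0]
    n_otus = codes.max() + 1
    sizes = np.unique(np.linspace(1, n, n_points).round().astype(int))
    rng = np.random.default_rng(seed)
    counts = np.empty((n_perm, sizes.size))
    for p in range(n_perm):
        perm = codes[rng.permutation(n)]
        first = np.full(n_otus, n, dtype=int)
        # first occurrence position of each OTU in this permutation
        np.minimum.at(first, perm, np.arange(n))
        counts[p] = np.searchsorted(np.sort(first), sizes, side="left")
    return pd.DataFrame(
        {
            "reads": sizes,
            "mean_otus": counts.mean(axis=0),
            "sd": counts.std(axis=0, ddof=0),
        }
    )
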