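"""Planktonic-origin classification of OTUs.

An OTU is called putatively planktonic if (a) its taxonomic assignment
falls in a listed phototrophic/planktonic taxon, or (b) its seed sequence
is at least 90% similar to an environmental sequence annotated as marine
plankton.  OTUs satisfying both are counted once; environmental categories
(marine plankton / marine sediment only / freshwater & soil) are recorded
alongside.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .taxonomy import (
    Assignment,
    Hit,
    ReferenceDB,
    ReferenceRecord,
    search,
)

HABITATS = ("marine_plankton", "marine_sediment", "freshwater_soil")

DEFAULT_ENV_THRESHOLD = 0.90


@dataclass(frozen=True)
class PlanktonCall:
    phototrophic: bool
    env_plankton: bool
    env_sediment_only: bool
    env_freshwater_soil: bool
    phototroph_group: str = ""

    @property
    def putative_planktonic(self) -> bool:
        return self.phototrophic or self.env_plankton


class PhototrophTable:
    """Taxon name -> display group for the known phototroph/planktonic taxa."""

    def __init__(self, groups: Mapping[str, str]):
        self.groups = dict(groups)

    @classmethod
    def load(cls, path: str | Path) -> "PhototrophTable":
        groups: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                groups[row[0].strip()] = row[1].strip() if len(row) > 1 else row[0].strip()
        return cls(groups)

    @classmethod
    def default(cls) -> "PhototrophTable":
        return cls.load(Path(__file__).parent / "data" / "phototrophs.tsv")


def load_env_db(fasta_path: str | Path, habitat_path: str | Path) -> ReferenceDB:
    """Environmental-sequence FASTA plus a required habitat TSV column.

    Habitats are stored as a one-element lineage so the generic search
    machinery applies unchanged.
    """
    habitats: dict[str, str] = {}
    with open(habitat_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rid, hab = row[0], row[1]
            if hab not in HABITATS:
                raise ValueError(f"unknown habitat {hab!r} for {rid!r}")
            habitats[rid] = hab
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in habitats:
            raise ValueError(f"env record {rec.id!r} lacks a habitat label")
        records.append(
            ReferenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                lineage=(("habitat", habitats[rec.id]),),
            )
        )
    return ReferenceDB(records)


def flag_phototrophic(
    assignment: Assignment, table: PhototrophTable
) -> tuple[bool, str]:
    """True (with display group) iff any lineage element is a listed taxon."""
    if assignment.status != "assigned":
        return False, ""
    for _, name in reversed(assignment.lineage):
        if name in table.groups:
            return True, table.groups[name]
    if assignment.label in table.groups:
        return True, table.groups[assignment.label]
    return False, ""


def env_classify(
    otu_seed: str,
    env_db: ReferenceDB,
    threshold: float = DEFAULT_ENV_THRESHOLD,
    hits: Sequence[Hit] | None = None,
) -> dict[str, bool]:
    """Habitat flags from environmental hits at or above the threshold.

    ``env_sediment_only`` means hits exist, none is marine plankton, and at
    least one is marine sediment.  Precomputed hits may be supplied.
    """
    if hits is None:
        hits = search(otu_seed, env_db)
    habs = {
        h.reference.name_at("habitat")
        for h in hits
        if h.similarity >= threshold
    }
    any_hits = bool(habs)
    plankton = "marine_plankton" in habs
    return {
        "env_plankton": plankton,
        "env_sediment_only": any_hits and not plankton and "marine_sediment" in habs,
        "env_freshwater_soil": "freshwater_soil" in habs,
    }


def classify_otu(
    seed_sequence: str,
    assignment: Assignment,
    env_db: ReferenceDB,
    phototrophs: PhototrophTable,
    threshold: float = DEFAULT_ENV_THRESHOLD,
    env_hits: Sequence[Hit] | None = None,
) -> PlanktonCall:
    photo, group = flag_phototrophic(assignment, phototrophs)
    env = env_classify(seed_sequence, env_db, threshold, hits=env_hits)
    return PlanktonCall(
        phototrophic=photo,
        phototroph_group=group,
        env_plankton=env["env_plankton"],
        env_sediment_only=env["env_sediment_only"],
        env_freshwater_soil=env["env_freshwater_soil"],
    )


def summarize_plankton(
    calls: Mapping[str, PlanktonCall],
    assignments: Mapping[str, Assignment],
    presence: pd.DataFrame,
    phototrophs: PhototrophTable,
) -> pd.DataFrame:
    """Per-sample planktonic summary.

    ``presence`` is an OTU x sample read-count table (index otu_id).  Rows:
    one per phototroph display group, the environmental categories (the
    marine-plankton row excludes OTUs already counted as phototrophic),
    the putative planktonic total (each OTU counted once), and the
    percentage of all assigned OTUs.
    """
    samples = list(presence.columns)
    groups: dict[str, None] = {}
    for g in phototrophs.groups.values():
        groups.setdefault(g)
    rows: dict[str, dict[str, float]] = {g: dict.fromkeys(samples, 0) for g in groups}
    for extra in (
        "Total phototrophic taxa",
        "Marine plankton",
        "Marine sediment only",
        "Freshwater & soil",
        "Putative planktonic OTUs",
        "Percentage of all assigned OTUs",
    ):
        rows[extra] = dict.fromkeys(samples, 0)

    for sample in samples:
        present = set(presence.index[presence[sample] > 0])
        assigned = [
            o for o in present
            if o in assignments and assignments[o].status == "assigned"
        ]
        n_assigned = len(assigned)
        n_photo = n_envp = n_sed = n_fw = n_plank = 0
        for otu in present:
            call = calls.get(otu)
            if call is None:
                continue
            if call.phototrophic:
                n_photo += 1
                grp = call.phototroph_group or "other"
                if grp in rows:
                    rows[grp][sample] += 1
            if call.env_plankton and not call.phototrophic:
                n_envp += 1
            if call.env_sediment_only:
                n_sed += 1
            if call.env_freshwater_soil:
                n_fw += 1
            if call.putative_planktonic:
                n_plank += 1
        rows["Total phototrophic taxa"][sample] = n_photo
        rows["Marine plankton"][sample] = n_envp
        rows["Marine sediment only"][sample] = n_sed
        rows["Freshwater & soil"][sample] = n_fw
        rows["Putative planktonic OTUs"][sample] = n_plank
        rows["Percentage of all assigned OTUs"][sample] = (
            round(100.0 * n_plank / n_assigned, 1) if n_assigned else 0.0
        )
    df = pd.DataFrame(rows).T
    df.index.name = "category"
    return df[samples]
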