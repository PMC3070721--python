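"""End-to-end pipeline: filter -> dereplicate -> triage -> cluster ->
assign -> plankton -> biogeography.

Produces the survey's standard report bundle: per-sample read accounting,
major-group OTU composition, planktonic-origin summary, occupancy classes
and region sharing, and the taxonomy profile of shared versus endemic
OTUs.  Every stage logs input/output counts; a fixed configuration yields
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import biogeo, otu as otu_mod, plankton as plankton_mod, taxonomy
from .seqio import PrimerPair, RawRead, screen_primers


@dataclass
class PipelineConfig:
    primers: PrimerPair
    region_map: Mapping[str, str]
    k: int = 3
    assignment_threshold: float = 0.80
    consensus_fraction: float = 0.75
    plankton_threshold: float = 0.90
    max_hits: int = 30
    min_similarity: float = taxonomy.DEFAULT_MIN_SIMILARITY
    drop_single_singletons: bool = False
    rarefaction_n_perm: int = 100
    seed: int = 1

    def assign_params(self) -> taxonomy.AssignParams:
        return taxonomy.AssignParams(
            assignment_threshold=self.assignment_threshold,
            consensus_fraction=self.consensus_fraction,
            max_hits=self.max_hits,
        )


@dataclass
class ReportBundle:
    read_counts: pd.DataFrame
    major_groups: pd.DataFrame
    plankton: pd.DataFrame
    occupancy: pd.DataFrame
    sharing: pd.DataFrame
    sharing_profile: pd.DataFrame
    otu_table: pd.DataFrame
    assignments: pd.DataFrame
    tag_assignments: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.read_counts.to_csv(outdir / "read_counts.tsv", sep="\t")
        self.major_groups.to_csv(outdir / "major_groups.tsv", sep="\t")
        self.plankton.to_csv(outdir / "plankton.tsv", sep="\t")
        self.occupancy.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
        self.sharing.drop(columns=["otu_ids"]).to_csv(
            outdir / "region_sharing.tsv", sep="\t", index=False
        )
        self.sharing_profile.to_csv(outdir / "sharing_profile.tsv", sep="\t")
        self.otu_table.to_csv(outdir / "otu_table.tsv", sep="\t", index=False)
        self.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        self.tag_assignments.to_csv(
            outdir / "tag_assignments.tsv", sep="\t", index=False
        )
        with open(outdir / "pipeline_log.jsonl", "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def run_pipeline(
    reads_by_sample: Mapping[str, Sequence[RawRead]],
    ref_db: taxonomy.ReferenceDB,
    env_db: taxonomy.ReferenceDB,
    config: PipelineConfig,
    phototrophs: plankton_mod.PhototrophTable | None = None,
    grouping: taxonomy.GroupingTable | None = None,
) -> ReportBundle:
    """Run every stage on demultiplexed per-sample reads.

    ``ref_db`` is the combined (eukaryotic + prokaryotic) V9 reference
    database used both for domain triage and for taxonomic assignment.
    """
    if phototrophs is None:
        phototrophs = plankton_mod.PhototrophTable.default()
    if grouping is None:
        grouping = taxonomy.GroupingTable.load(
            Path(__file__).parent / "data" / "major_groups.tsv"
        )
    params = config.assign_params()
    samples = list(reads_by_sample)
    missing = [s for s in samples if s not in config.region_map]
    if missing:
        raise ValueError(f"samples without region labels: {missing}")
    log: list[dict] = []

    # --- stage 1: primer screen ------------------------------------------
    kept_by_sample: dict[str, list] = {}
    total_raw: dict[str, int] = {}
    for s in samples:
        kept, rejected = screen_primers(reads_by_sample[s], config.primers)
        kept_by_sample[s] = kept
        total_raw[s] = len(kept) + len(rejected)
        log.append(
            {"stage": "filter", "sample": s, "in": total_raw[s],
             "kept": len(kept), "rejected": len(rejected)}
        )

    # --- stage 2: strict dereplication (pooled) ---------------------------
    all_kept = [r for s in samples for r in kept_by_sample[s]]
    tags = otu_mod.dereplicate(all_kept)
    log.append({"stage": "dereplicate", "reads": len(all_kept), "tags": len(tags)})

    # --- stage 3: search + domain triage per tag --------------------------
    tag_hits = [
        taxonomy.search(
            t.sequence, ref_db,
            max_hits=config.max_hits, min_similarity=config.min_similarity,
        )
        for t in tags
    ]
    tag_class = [taxonomy.classify_domain(h, params) for h in tag_hits]
    domain_counts = {
        s: {"eukaryotic": 0, "archaeal": 0, "bacterial": 0, "non_rRNA": 0}
        for s in samples
    }
    for t, cls in zip(tags, tag_class):
        for s, c in t.per_sample.items():
            domain_counts[s][cls] += c
    log.append(
        {"stage": "triage",
         **{k: sum(d[k] for d in domain_counts.values())
            for k in ("eukaryotic", "archaeal", "bacterial", "non_rRNA")}}
    )

    # --- stage 4: greedy clustering of eukaryotic tags --------------------
    euk_idx = [i for i, cls in enumerate(tag_class) if cls == "eukaryotic"]
    euk_tags = [tags[i] for i in euk_idx]
    euk_hits = {tags[i].sequence: tag_hits[i] for i in euk_idx}
    otus = otu_mod.greedy_cluster(euk_tags, config.k)
    dropped: list = []
    if config.drop_single_singletons:
        otus, dropped = otu_mod.drop_single_singletons(otus)
    log.append(
        {"stage": "cluster", "k": config.k, "tags": len(euk_tags),
         "otus": len(otus), "single_singletons_dropped": len(dropped)}
    )
    table = otu_mod.otu_table(otus, samples)
    otu_ids = list(table["otu_id"])

    # --- stage 5: consensus assignment of OTU seeds -----------------------
    assignments: dict[str, taxonomy.Assignment] = {}
    categories: dict[str, str] = {}
    for oid, o in zip(otu_ids, otus):
        a = taxonomy.assign_consensus(euk_hits[o.seed.sequence], params)
        assignments[oid] = a
        categories[oid] = taxonomy.rollup_major_group(a, grouping)
    assign_df = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "status": [assignments[o].status for o in otu_ids],
            "label": [assignments[o].label for o in otu_ids],
            "rank": [assignments[o].rank for o in otu_ids],
            "best_similarity": [assignments[o].best_similarity for o in otu_ids],
            "major_group": [categories[o] for o in otu_ids],
        }
    )
    # per-tag assignments (the survey assigns unique sequences, not reads)
    tag_assign_rows = []
    for i in euk_idx:
        a = taxonomy.assign_consensus(tag_hits[i], params)
        tag_assign_rows.append(
            {
                "rep_id": tags[i].rep_id,
                "abundance": tags[i].abundance,
                "status": a.status,
                "label": a.label,
                "rank": a.rank,
                "best_similarity": a.best_similarity,
            }
        )
    tag_assign_df = pd.DataFrame(
        tag_assign_rows,
        columns=["rep_id", "abundance", "status", "label", "rank", "best_similarity"],
    )
    log.append(
        {"stage": "assign",
         "assigned": int((assign_df["status"] == "assigned").sum()),
         "unassigned": int((assign_df["status"] == "unassigned").sum()),
         "undetermined": int((assign_df["status"] == "undetermined").sum())}
    )

    # --- stage 6: plankton classification ---------------------------------
    incidence = table.set_index("otu_id")[samples]
    calls: dict[str, plankton_mod.PlanktonCall] = {}
    for oid, o in zip(otu_ids, otus):
        calls[oid] = plankton_mod.classify_otu(
            o.seed.sequence, assignments[oid], env_db, phototrophs,
            threshold=config.plankton_threshold,
        )
    plankton_table = plankton_mod.summarize_plankton(
        calls, assignments, incidence, phototrophs
    )
    log.append(
        {"stage": "plankton",
         "putative_planktonic": sum(c.putative_planktonic for c in calls.values())}
    )

    # --- stage 7: biogeography --------------------------------------------
    inc = biogeo.IncidenceTable(counts=incidence, region_map=dict(config.region_map))
    occupancy = biogeo.occupancy(inc)
    sharing = biogeo.region_sharing(inc)
    profile = biogeo.sharing_taxonomy_profile(
        sharing,
        {o: categories[o] for o in otu_ids},
        {o: calls[o].putative_planktonic for o in otu_ids},
        scope="all",
    )

    # --- report tables -----------------------------------------------------
    status_by_sample = {
        s: {"assigned": 0, "unassigned": 0, "undetermined": 0} for s in samples
    }
    group_rows = {
        g: dict.fromkeys(samples, 0)
        for g in grouping.categories() + ["Undetermined"]
    }
    for oid in otu_ids:
        present = incidence.loc[oid]
        for s in samples:
            if present[s] > 0:
                status_by_sample[s][assignments[oid].status] += 1
                cat = categories[oid]
                if cat != "Unassigned":
                    group_rows.setdefault(cat, dict.fromkeys(samples, 0))
                    group_rows[cat][s] += 1
    major = pd.DataFrame(group_rows).T
    major.loc["Subtotal assigned"] = [
        status_by_sample[s]["assigned"] + status_by_sample[s]["undetermined"]
        for s in samples
    ]
    major.loc["Unassigned"] = [status_by_sample[s]["unassigned"] for s in samples]
    major.loc["Total"] = major.loc["Subtotal assigned"] + major.loc["Unassigned"]
    major.index.name = "major_group"

    read_counts = pd.DataFrame(
        {
            s: {
                "total_reads": total_raw[s],
                "primer_screened_reads": len(kept_by_sample[s]),
                "archaeal_reads": domain_counts[s]["archaeal"],
                "bacterial_reads": domain_counts[s]["bacterial"],
                "non_rRNA_reads": domain_counts[s]["non_rRNA"],
                "eukaryotic_reads": domain_counts[s]["eukaryotic"],
                "unique_tags": sum(
                    1 for t in euk_tags if t.per_sample.get(s, 0) > 0
                ),
                "otus": int((incidence[s] > 0).sum()),
                "assigned_otus": status_by_sample[s]["assigned"]
                + status_by_sample[s]["undetermined"],
                "unassigned_otus": status_by_sample[s]["unassigned"],
            }
            for s in samples
        }
    )
    read_counts.index.name = "count"

    return ReportBundle(
        read_counts=read_counts,
        major_groups=major,
        plankton=plankton_table,
        occupancy=occupancy,
        sharing=sharing,
        sharing_profile=profile,
        otu_table=table,
        assignments=assign_df,
        tag_assignments=tag_assign_df,
        log=log,
    )
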