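"""Synthetic reference databases, communities, and 454-style reads.

The generator emulates the data regime of a two-region deep-sea sediment
V9 metabarcoding survey with known ground truth:

* a hierarchical reference taxonomy whose sequence divergence grows with
  rank distance (congeneric species a couple of percent apart, genera far
  enough apart to be resolvable at the 80% similarity floor);
* six samples in two regions (three per region) with a stated fraction of
  "bipolar" genera present in both regions and the rest region-endemic;
* skewed (lognormal) per-sample abundances;
* 454-style noise dominated by homopolymer run-length miscalls whose
  probability grows with run length, plus a low per-base substitution
  rate;
* archaeal / bacterial / non-rRNA contaminant reads at the proportions a
  broad-specificity eukaryotic primer pair captures;
* an environmental-sequence database with habitat labels and a phototroph
  taxon list, so planktonic-origin classification has ground truth
  (a stated fraction of genera is planktonic, half via phototrophic taxa
  and half via marine-plankton environmental matches).

Every read, tag and genus is traceable to its truth row, and a fixed seed
reproduces the corpus byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import PrimerPair, RawRead
from .taxonomy import ReferenceDB, ReferenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PHOTOTROPH_PHYLA = (
    "Bacillariophyta",
    "Chlorophyta",
    "Rhodophyta",
    "Haptophyta",
    "Picobiliphyta",
    "Pelagophyceae",
    "Dictyochophyceae",
    "Raphidophyceae",
)

HETEROTROPH_PHYLA = (
    "Ciliophora",
    "Dinophyceae",
    "Cercozoa",
    "Euglenozoa",
    "Metazoa",
    "Fungi",
    "Amoebozoa",
    "Chrysophyceae",
    "Labyrinthulea",
    "Telonemia",
    "Foraminifera",
    "Apusozoa",
)

_KINGDOM = {
    "Ciliophora": "Alveolata", "Dinophyceae": "Alveolata",
    "Cercozoa": "Rhizaria", "Foraminifera": "Rhizaria",
    "Euglenozoa": "Excavata", "Metazoa": "Opisthokonta",
    "Fungi": "Opisthokonta", "Amoebozoa": "Amoebozoa",
    "Chrysophyceae": "Stramenopiles", "Labyrinthulea": "Stramenopiles",
    "Bacillariophyta": "Stramenopiles", "Pelagophyceae": "Stramenopiles",
    "Dictyochophyceae": "Stramenopiles", "Raphidophyceae": "Stramenopiles",
    "Telonemia": "Hacrobia", "Haptophyta": "Hacrobia",
    "Picobiliphyta": "Hacrobia", "Chlorophyta": "Archaeplastida",
    "Rhodophyta": "Archaeplastida", "Apusozoa": "Apusozoa",
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic corpus.

    ``divergence`` gives the expected pairwise divergence between sibling
    taxa at each rank and must increase family > genus > species.
    ``hp_indel_rate`` is the per-run miscall coefficient: a run of length
    L is lengthened or shortened with probability min(0.5, rate*(L-1)).
    """

    n_taxa: int = 120  # community genera
    species_per_genus: int = 3
    v9_length_mean: float = 130.0
    v9_length_sd: float = 10.0
    # sibling divergence per rank: congeners ~2% apart; sibling genera far
    # enough that their pairwise similarity stays below the 80% assignment
    # floor even in the sampling tail (the V9 region is hypervariable and
    # the reference genera are meant to be resolvable at that floor)
    divergence: dict = field(
        default_factory=lambda: {"family": 0.70, "genus": 0.45, "species": 0.02}
    )
    samples: tuple[tuple[str, str], ...] = (
        ("DSE1", "ANT"), ("DSE2", "ANT"), ("DSE3", "ANT"),
        ("DSE4", "ARC"), ("DSE5", "ARC"), ("DSE6", "ARC"),
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    shared_fraction: float = 0.4
    presence_prob: float = 0.8
    planktonic_fraction: float = 0.4
    hp_indel_rate: float = 0.01
    sub_rate: float = 0.001
    reads_per_sample: int = 10_000
    frac_archaea: float = 0.035
    frac_bacteria: float = 0.091
    frac_non_rrna: float = 0.0025
    frac_no_primer: float = 0.01
    frac_ambiguous: float = 0.002
    n_archaea: int = 15
    n_bacteria: int = 25
    primers: PrimerPair = field(
        default_factory=lambda: PrimerPair(
            proximal="TTGTACACACCGCCC", distal="GTAGGTGAACCTGCRGAAGG"
        )
    )
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "shared_fraction", "presence_prob", "planktonic_fraction",
            "hp_indel_rate", "sub_rate", "frac_archaea", "frac_bacteria",
            "frac_non_rrna", "frac_no_primer", "frac_ambiguous",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        d = self.divergence
        if not d["family"] > d["genus"] > d["species"] > 0:
            raise ValueError(
                "divergence must increase with rank distance "
                "(family > genus > species > 0)"
            )


@dataclass
class ReferenceBundle:
    """Everything the pipeline needs, plus genus-level ground truth."""

    euk_records: list[ReferenceRecord]
    prok_records: list[ReferenceRecord]
    env_db: ReferenceDB
    genus_truth: pd.DataFrame  # genus, phylum, planktonic, route, region_class
    community: dict[str, ReferenceRecord]  # genus -> community species record

    @property
    def combined_db(self) -> ReferenceDB:
        return ReferenceDB(self.euk_records + self.prok_records)

    @property
    def euk_db(self) -> ReferenceDB:
        return ReferenceDB(self.euk_records)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    out = seq.copy()
    sites = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_reference(params: SimParams) -> ReferenceBundle:
    """Generate reference, environmental and contaminant databases.

    Each community genus carries ``species_per_genus`` reference species;
    the first species of each genus is the community member that actually
    sheds reads.  Branch substitution rates are derived from the sibling
    divergences so that congeners sit ~2% apart and genera ~30%+ apart.
    """
    rng = np.random.default_rng(params.seed)
    d = params.divergence
    b_species = d["species"] / 2
    b_genus = d["genus"] / 2 - b_species
    b_family = d["family"] / 2 - b_genus - b_species
    if min(b_species, b_genus, b_family) <= 0:
        raise ValueError("divergence settings imply non-positive branch rates")

    n = params.n_taxa
    n_plank = round(params.planktonic_fraction * n)
    n_photo = n_plank // 2
    n_envonly = n_plank - n_photo

    # genus -> phylum: phototroph-route genera on phototrophic phyla,
    # everything else on heterotrophic phyla, round-robin
    phyla = [PHOTOTROPH_PHYLA[i % len(PHOTOTROPH_PHYLA)] for i in range(n_photo)]
    phyla += [
        HETEROTROPH_PHYLA[i % len(HETEROTROPH_PHYLA)]
        for i in range(n - n_photo)
    ]
    routes = ["phototroph"] * n_photo + ["env"] * n_envonly + ["none"] * (n - n_plank)

    # region structure
    n_shared = round(params.shared_fraction * n)
    regions = sorted({r for _, r in params.samples})
    region_class = ["bipolar"] * n_shared
    for i in range(n - n_shared):
        region_class.append(regions[i % len(regions)])
    rng.shuffle(region_class)

    # phylum root sequences (per phylum, one draw of the V9 length)
    phylum_root: dict[str, np.ndarray] = {}
    for ph in PHOTOTROPH_PHYLA + HETEROTROPH_PHYLA:
        length = int(
            np.clip(
                rng.normal(params.v9_length_mean, params.v9_length_sd), 80, 200
            )
        )
        phylum_root[ph] = _random_seq(rng, length)

    euk_records: list[ReferenceRecord] = []
    env_records: list[ReferenceRecord] = []
    community: dict[str, ReferenceRecord] = {}
    truth_rows = []
    family_seq: dict[tuple[str, int], np.ndarray] = {}
    genera_in_phylum: dict[str, int] = {}

    for gi in range(n):
        ph = phyla[gi]
        idx_in_ph = genera_in_phylum.get(ph, 0)
        genera_in_phylum[ph] = idx_in_ph + 1
        fam_idx = idx_in_ph // 3  # three genera per family
        fam_key = (ph, fam_idx)
        if fam_key not in family_seq:
            family_seq[fam_key] = _mutate(rng, phylum_root[ph], b_family)
        genus = f"Gen{gi + 1:04d}"
        family = f"{ph}_fam{fam_idx + 1:03d}"
        genus_seq = _mutate(rng, family_seq[fam_key], b_genus)
        lineage_base = (
            ("domain", "Eukaryota"),
            ("kingdom", _KINGDOM[ph]),
            ("phylum", ph),
            ("class", f"{ph}_class"),
            ("order", f"{ph}_ord{fam_idx + 1:03d}"),
            ("family", family),
            ("genus", genus),
        )
        for si in range(params.species_per_genus):
            sp_seq = _mutate(rng, genus_seq, b_species)
            rec = ReferenceRecord(
                id=f"{genus}_sp{si + 1}",
                sequence=_to_str(sp_seq),
                lineage=lineage_base + (("species", f"{genus}_sp{si + 1}"),),
                source_db_version="synthetic-v1",
            )
            euk_records.append(rec)
            if si == 0:
                community[genus] = rec

        route = routes[gi]
        # environmental mirrors: planktonic 'env' genera -> marine plankton;
        # a rotation of the remaining benthic genera -> sediment / freshwater
        habitat = ""
        comm_seq = np.frombuffer(
            community[genus].sequence.encode(), dtype=np.uint8
        )
        if route == "env":
            habitat = "marine_plankton"
        elif route == "none":
            habitat = ["marine_sediment", "", "freshwater_soil", ""][gi % 4]
        if habitat:
            env_records.append(
                ReferenceRecord(
                    id=f"env_{genus}",
                    sequence=_to_str(_mutate(rng, comm_seq, 0.02)),
                    lineage=(("habitat", habitat),),
                )
            )
        truth_rows.append(
            {
                "genus": genus,
                "phylum": ph,
                "family": family,
                "planktonic": route in ("phototroph", "env"),
                "route": route,
                "region_class": region_class[gi],
                "env_habitat": habitat,
                "community_species": community[genus].id,
            }
        )

    prok_records: list[ReferenceRecord] = []
    for dom, n_dom, tag in (
        ("Archaea", params.n_archaea, "Arc"),
        ("Bacteria", params.n_bacteria, "Bac"),
    ):
        root = _random_seq(
            rng, int(np.clip(rng.normal(params.v9_length_mean, params.v9_length_sd), 80, 200))
        )
        for i in range(n_dom):
            prok_records.append(
                ReferenceRecord(
                    id=f"{tag}{i + 1:03d}",
                    sequence=_to_str(_mutate(rng, root, 0.15)),
                    lineage=(
                        ("domain", dom),
                        ("kingdom", f"{dom}_kingdom"),
                        ("phylum", f"{dom}_phylum{i % 4 + 1}"),
                        ("genus", f"{tag}Gen{i + 1:03d}"),
                    ),
                )
            )

    return ReferenceBundle(
        euk_records=euk_records,
        prok_records=prok_records,
        env_db=ReferenceDB(env_records),
        genus_truth=pd.DataFrame(truth_rows),
        community=community,
    )


def _runs(seq: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of length >= 2."""
    out = []
    start = 0
    for i in range(1, seq.size + 1):
        if i == seq.size or seq[i] != seq[start]:
            if i - start >= 2:
                out.append((start, i - start))
            start = i
    return out


def _apply_454_noise(
    rng: np.random.Generator,
    seq: np.ndarray,
    runs: list[tuple[int, int]],
    n_reads: int,
    hp_rate: float,
    sub_rate: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Emit ``n_reads`` noisy copies of ``seq``.

    Returns the read strings plus per-read counts of homopolymer events
    and substitutions.  Run miscalls change a run's length by +-1 with
    probability min(0.5, hp_rate * (length - 1)); substitutions hit each
    base independently at ``sub_rate``.
    """
    probs = np.array([min(0.5, hp_rate * (ln - 1)) for _, ln in runs])
    if probs.size:
        hp_events = rng.random((n_reads, probs.size)) < probs
        hp_dirs = rng.integers(0, 2, size=(n_reads, probs.size))  # 0=-1, 1=+1
    else:
        hp_events = np.zeros((n_reads, 0), dtype=bool)
        hp_dirs = hp_events.astype(int)
    n_subs = rng.binomial(seq.size, sub_rate, size=n_reads)
    clean = _to_str(seq)
    reads: list[str] = []
    for r in range(n_reads):
        if not hp_events[r].any() and n_subs[r] == 0:
            reads.append(clean)
            continue
        arr = seq.copy()
        if n_subs[r]:
            arr = arr.copy()
            for i in rng.choice(seq.size, size=n_subs[r], replace=False):
                choices = _BASES[_BASES != arr[i]]
                arr[i] = choices[rng.integers(0, 3)]
        if hp_events[r].any():
            pieces: list[np.ndarray] = []
            prev = 0
            for ri, (start, ln) in enumerate(runs):
                if not hp_events[r, ri]:
                    continue
                pieces.append(arr[prev:start])
                new_len = ln + (1 if hp_dirs[r, ri] else -1)
                pieces.append(np.repeat(seq[start], new_len))
                prev = start + ln
            pieces.append(arr[prev:])
            arr = np.concatenate(pieces)
        reads.append(_to_str(arr))
    return reads, hp_events.sum(axis=1), n_subs


def simulate_reads(
    params: SimParams, bundle: ReferenceBundle
) -> tuple[dict[str, list[RawRead]], pd.DataFrame]:
    """Simulate per-sample read sets with full per-read ground truth.

    Reads are full amplicons (proximal primer + noisy V9 insert + distal
    primer).  A small fraction lose their distal primer or carry an
    ambiguous base, emulating reads the primer-anchoring filter must
    reject.
    """
    rng = np.random.default_rng(params.seed + 1)
    distal_concrete = "".join(
        c if c in "ACGT" else {"R": "A", "Y": "C"}.get(c, "A")
        for c in params.primers.distal
    )
    prox = params.primers.proximal

    truth = bundle.genus_truth
    genus_meta = truth.set_index("genus")
    run_cache: dict[str, tuple[np.ndarray, list[tuple[int, int]]]] = {}

    def seq_and_runs(seq: str):
        if seq not in run_cache:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            run_cache[seq] = (arr, _runs(arr))
        return run_cache[seq]

    reads_by_sample: dict[str, list[RawRead]] = {}
    rows = []
    for sample, region in params.samples:
        # which genera shed reads into this sample
        candidates = [
            g for g in truth["genus"]
            if genus_meta.loc[g, "region_class"] in ("bipolar", region)
        ]
        present = [
            g for g in candidates if rng.random() < params.presence_prob
        ]
        weights = rng.lognormal(
            params.lognormal_mu, params.lognormal_sigma, size=len(present)
        )
        class_p = np.array(
            [params.frac_archaea, params.frac_bacteria, params.frac_non_rrna]
        )
        n_total = params.reads_per_sample
        n_arc, n_bac, n_junk = rng.multinomial(n_total, np.append(class_p, 1 - class_p.sum()))[:3]
        n_euk = n_total - n_arc - n_bac - n_junk
        euk_counts = rng.multinomial(n_euk, weights / weights.sum())

        sample_reads: list[RawRead] = []
        counter = itertools.count()

        def emit(insert: str, category: str, species_id: str, genus: str,
                 n_hp: int, n_sub: int) -> None:
            idx = next(counter)
            rid = f"{sample}_r{idx:06d}"
            u = rng.random()
            primer_ok = True
            clean = True
            seq = prox + insert + distal_concrete
            if u < params.frac_no_primer:
                seq = seq[: len(seq) - rng.integers(3, len(distal_concrete) + 1)]
                primer_ok = False
                clean = False
            elif u < params.frac_no_primer + params.frac_ambiguous:
                pos = len(prox) + rng.integers(0, len(insert))
                seq = seq[:pos] + "N" + seq[pos + 1:]
                clean = False
            sample_reads.append(RawRead(id=rid, sequence=seq, sample=sample))
            ph = genus_meta.loc[genus, "phylum"] if genus else ""
            rows.append(
                {
                    "read_id": rid, "sample": sample, "region": region,
                    "category": category, "species_id": species_id,
                    "genus": genus, "phylum": ph,
                    "planktonic": bool(genus_meta.loc[genus, "planktonic"]) if genus else False,
                    "clean": clean, "n_hp_events": n_hp, "n_subs": n_sub,
                }
            )

        for g, cnt in zip(present, euk_counts):
            if cnt == 0:
                continue
            rec = bundle.community[g]
            arr, runs = seq_and_runs(rec.sequence)
            noisy, n_hp, n_sub = _apply_454_noise(
                rng, arr, runs, int(cnt), params.hp_indel_rate, params.sub_rate
            )
            for read_seq, h, s in zip(noisy, n_hp, n_sub):
                emit(read_seq, "eukaryotic", rec.id, g, int(h), int(s))

        for n_class, recs, cat in (
            (n_arc, [r for r in bundle.prok_records if r.domain == "Archaea"], "archaeal"),
            (n_bac, [r for r in bundle.prok_records if r.domain == "Bacteria"], "bacterial"),
        ):
            if n_class == 0:
                continue
            w = rng.lognormal(0, 1.0, size=len(recs))
            counts = rng.multinomial(n_class, w / w.sum())
            for rec, cnt in zip(recs, counts):
                if cnt == 0:
                    continue
                arr, runs = seq_and_runs(rec.sequence)
                noisy, n_hp, n_sub = _apply_454_noise(
                    rng, arr, runs, int(cnt), params.hp_indel_rate, params.sub_rate
                )
                for read_seq, h, s in zip(noisy, n_hp, n_sub):
                    emit(read_seq, cat, rec.id, "", int(h), int(s))

        for _ in range(n_junk):
            emit(_to_str(_random_seq(rng, 130)), "non_rRNA", "", "", 0, 0)

        # interleave deterministically so file order is not grouped by taxon
        order = rng.permutation(len(sample_reads))
        reads_by_sample[sample] = [sample_reads[i] for i in order]

    return reads_by_sample, pd.DataFrame(rows)


def write_corpus(
    params: SimParams,
    bundle: ReferenceBundle,
    reads_by_sample: dict[str, list[RawRead]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write the whole synthetic corpus as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .seqio import write_plain_fasta

    for sample, reads in reads_by_sample.items():
        write_plain_fasta(
            ((r.id, r.sequence) for r in reads), outdir / f"{sample}.fasta"
        )
    write_plain_fasta(
        ((r.id, r.sequence) for r in bundle.euk_records + bundle.prok_records),
        outdir / "reference.fasta",
    )
    with open(outdir / "reference_taxonomy.tsv", "w") as fh:
        for r in bundle.euk_records + bundle.prok_records:
            fh.write(f"{r.id}\t{';'.join(n for _, n in r.lineage)}\n")
    write_plain_fasta(
        ((r.id, r.sequence) for r in bundle.env_db.records), outdir / "env.fasta"
    )
    with open(outdir / "env_habitats.tsv", "w") as fh:
        for r in bundle.env_db.records:
            fh.write(f"{r.id}\t{r.name_at('habitat')}\n")
    bundle.genus_truth.to_csv(outdir / "genus_truth.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
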