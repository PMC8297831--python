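"""Synthetic mobilome datasets with ground-truth labels.

The generator emulates the statistical structure the downstream stages
assume: genomes of 104-735 kbp whose planted ATPase gene count grows
linearly with length (Poisson around rate x length), proteins carrying
literal Walker-A/Walker-B motifs at the canonical ~100-residue spacing,
composite proteins with 1-3 ATPase domains plus a category-bearing
functional domain, duplicate gene calls at identical coordinates, contigs
with majority-cellular best-hit taxonomy, and conserved +-3-gene
neighborhoods (operon-like, overlapping-pair, or isolated) backed by a
tabular homology table at stringent e-values.

Background (non-ATPase) protein sequences are drawn i.i.d. from uniform
residue frequencies with Walker-A matches rejected and resampled, so the
scanner's false-positive rate on background is measurable and clean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from mobatp import io as mio
from mobatp.motifs import WALKER_A_LEN, _WALKER_A_RE, scan_walker_a
from mobatp.records import DomainHit, GeneRecord

AMINO20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

#: ATPase domain names planted in domain tables (all carry ATP/AAA keywords)
ATPASE_DOMAIN_NAMES = ["AAA_22", "AAA_18", "ATPase_2", "AAA_14", "ATP_bind_1"]

#: functional domain names and the category they imply
FUNCTIONAL_DOMAIN_POOL = [
    ("Peptidase_S14", "protease"),
    ("Lon_C", "protease"),
    ("PIN_4", "nuclease"),
    ("LAGLIDADG_1", "nuclease"),
    ("HNH_3", "nuclease"),
    ("DEAD", "helicase"),
    ("SNF2_N", "helicase"),
    ("RNA_polymerase_N", "polymerase"),
    ("Prim_primase", "polymerase"),
    ("DnaK_C", "chaperone"),
    ("HSP70", "chaperone"),
    ("Terminase_6", "transport/packaging"),
    ("ABC_membrane", "transport/packaging"),
    ("VirE_N", "virE"),
    ("MutS_V", "DNA-repair"),
    ("ParA_partition", "nucleotide-binding"),
]

UNKNOWN_DOMAIN_NAMES = ["DUF2791", "DUF4011", "DUF3854"]

#: length in residues of one planted ATPase domain block: Walker-A near the
#: start, Walker-B 100 residues after it, plus flanking sequence
DOMAIN_BLOCK_AA = 140

_HYDRO = "VILFM"


@dataclass
class SimConfig:
    """Study conditions of the synthetic census (defaults mirror the survey)."""

    n_genomes: int = 353
    length_range_kbp: tuple[float, float] = (104.0, 735.0)
    atpase_rate_per_100kbp: float = 4.435
    mean_gene_length_bp: float = 733.0
    composite_fraction: float = 0.09
    multi_atpase_max: int = 3
    n_duplicate_candidates: int = 57
    cellular_contig_fraction: float = 0.44
    neighborhood_conserved_fraction: float = 0.66
    overlap_pair_fraction: float = 1.0
    unknown_category_fraction: float = 0.384
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range_kbp
        if lo > hi or lo <= 0:
            raise ValueError(f"bad genome length range ({lo}, {hi}) kbp")
        if self.atpase_rate_per_100kbp < 0:
            raise ValueError("ATPase rate must be >= 0")
        for name in (
            "composite_fraction",
            "cellular_contig_fraction",
            "neighborhood_conserved_fraction",
            "overlap_pair_fraction",
            "unknown_category_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_gene_length_bp >= lo * 1000:
            raise ValueError(
                "mean gene length exceeds the smallest genome; infeasible config"
            )
        if self.mean_gene_length_bp < 250:
            raise ValueError("mean gene length too short to host a protein gene")
        if self.multi_atpase_max < 1:
            raise ValueError("multi_atpase_max must be >= 1")


@dataclass
class SimPaths:
    proteins_fasta: Path
    gene_table: Path
    domain_table: Path
    homology_table: Path
    taxonomy_table: Path
    genome_table: Path
    truth_json: Path


@dataclass
class SimTruth:
    """Ground-truth labels consistent with the emitted files."""

    config: dict
    genomes: dict  # genome_id -> {length_kbp, planted_atpase_count, gc_percent, cellular}
    atpase_proteins: dict  # protein_id -> label dict
    context: dict  # focal_id -> {type, partner, overlap, family}
    duplicates: dict  # duplicate gene_id -> original gene_id
    n_background: int = 0

    @property
    def atpase_ids(self) -> set[str]:
        return set(self.atpase_proteins)

    def composite_ids(self) -> set[str]:
        return {
            pid for pid, lab in self.atpase_proteins.items() if lab["is_composite"]
        }

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def simulate_genome_counts(
    n_genomes: int,
    length_range_kbp: tuple[float, float],
    rate_per_100kbp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw genome lengths and planted ATPase-protein counts.

    Lengths are uniform on the given range; counts are Poisson with mean
    rate x length / 100 kbp. This is the count model every sequence-level
    simulation plants, exposed separately so regression-recovery experiments
    can run at scale.
    """
    lo, hi = length_range_kbp
    lengths = rng.uniform(lo, hi, size=n_genomes)
    counts = rng.poisson(rate_per_100kbp * lengths / 100.0)
    return lengths, counts


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    """A uniform-residue protein with Walker-A windows rejected and resampled."""
    while True:
        seq = AMINO20[rng.integers(0, 20, size=n_aa)].tobytes().decode()
        if not _WALKER_A_RE.search(seq):
            return seq


def _plant_atpase_protein(
    rng: np.random.Generator, n_domains: int, composite: bool
) -> tuple[str, list[tuple[int, int]]]:
    """Build a protein with one Walker-A/B pair per domain block.

    Returns the sequence and the 1-based (start, end) span of each block.
    The sequence is resampled until the Walker-A count equals the number of
    planted domains, so motif-mode domain counts match the truth labels.
    """
    tail = 60 if composite else 12
    n_aa = n_domains * DOMAIN_BLOCK_AA + tail
    while True:
        seq = list(_random_protein(rng, n_aa))
        spans = []
        for d in range(n_domains):
            block = d * DOMAIN_BLOCK_AA
            pa = block + 10  # 0-based Walker-A start
            seq[pa] = "G"
            seq[pa + 3] = "G"
            seq[pa + 5] = "G"
            seq[pa + 6] = "K"
            seq[pa + 7] = "T" if rng.random() < 0.5 else "S"
            # Walker-B starts 100 residues after the Walker-A end
            pb = pa + WALKER_A_LEN + 100 - 1
            for i in range(4):
                seq[pb + i] = _HYDRO[rng.integers(0, len(_HYDRO))]
            seq[pb + 4] = "D"
            spans.append((block + 1, block + DOMAIN_BLOCK_AA))
        s = "".join(seq)
        if len(scan_walker_a(s)) == n_domains:
            return s, spans


def _domain_evalue(rng: np.random.Generator) -> float:
    return float(10.0 ** rng.uniform(-40, -5))


def _outfmt6_row(q: str, s: str, evalue: float, bitscore: float) -> tuple:
    return (q, s, 97.5, 180, 4, 0, 1, 180, 1, 180, evalue, bitscore)


def simulate_dataset(
    config: SimConfig, outdir: str | Path
) -> tuple[SimPaths, SimTruth]:
    """Emit a full synthetic mobilome dataset plus its ground truth.

    Files written under ``outdir``: proteins.faa, genes.tsv, domains.tsv,
    homology.tsv (tabular BLAST), taxonomy.tsv, genomes.tsv and truth.json.
    The same config and seed produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lengths_kbp, atpase_counts = simulate_genome_counts(
        config.n_genomes,
        config.length_range_kbp,
        config.atpase_rate_per_100kbp,
        rng,
    )
    mean_bg_aa = max(50, int(round((config.mean_gene_length_bp - 76) / 3)))

    genes: list[GeneRecord] = []
    fasta: list[tuple[str, str]] = []
    domain_hits: list[DomainHit] = []
    taxonomy_rows: list[tuple[str, str, str]] = []
    homology_rows: list[tuple] = []
    truth_genomes: dict = {}
    atpase_labels: dict = {}
    context_truth: dict = {}
    duplicates: dict = {}
    n_background = 0
    composite_genes: list[GeneRecord] = []  # originals only
    planted_counts: list[int] = []
    db_counter = 0

    cellular_flags = rng.random(config.n_genomes) < config.cellular_contig_fraction

    for g in range(config.n_genomes):
        gid = f"G{g:04d}"
        length_bp = int(round(lengths_kbp[g] * 1000))
        n_genes = max(1, int(round(length_bp / config.mean_gene_length_bp)))
        n_atp = int(min(atpase_counts[g], n_genes))
        planted_counts.append(n_atp)
        atp_idx = set(rng.choice(n_genes, size=n_atp, replace=False).tolist())

        # per-gene plans: (is_atpase, is_composite, n_domains)
        plans = []
        for i in range(n_genes):
            if i in atp_idx:
                comp = bool(rng.random() < config.composite_fraction)
                nd = int(rng.integers(1, config.multi_atpase_max + 1)) if comp else 1
                plans.append((True, comp, nd))
            else:
                plans.append((False, False, 0))

        # context plans for composite foci (decided before layout so pair
        # partners can be made small)
        pair_partner_aa: dict[int, int] = {}
        ctx_plan: dict[int, dict] = {}
        p_cons = config.neighborhood_conserved_fraction
        for i, (is_atp, comp, nd) in enumerate(plans):
            if not comp:
                continue
            u = rng.random()
            if u < p_cons / 2:
                ctx = "conserved_operon"
            elif u < p_cons:
                ctx = "conserved_pair"
            else:
                ctx = "isolated"
            if ctx == "conserved_pair" and i + 1 >= n_genes:
                ctx = "isolated"
            entry = {"type": ctx, "partner": None, "overlap": False}
            if ctx == "conserved_pair":
                entry["partner"] = i + 1
                entry["overlap"] = bool(rng.random() < config.overlap_pair_fraction)
                pair_partner_aa[i + 1] = 60  # small overlapping partner
            ctx_plan[i] = entry

        # amino-acid lengths and sequences
        aa_lengths = []
        seqs: list[str] = []
        spans_per_gene: list[list[tuple[int, int]]] = []
        for i, (is_atp, comp, nd) in enumerate(plans):
            if is_atp:
                seq, spans = _plant_atpase_protein(rng, nd, comp)
            else:
                n_aa = pair_partner_aa.get(
                    i,
                    int(np.clip(rng.normal(mean_bg_aa, 0.3 * mean_bg_aa), 50, 4 * mean_bg_aa)),
                )
                seq, spans = _random_protein(rng, int(n_aa)), []
            aa_lengths.append(len(seq))
            seqs.append(seq)
            spans_per_gene.append(spans)

        # coordinate layout: cursor walk with small intergenic gaps
        cursor = 1
        coords = []
        for i in range(n_genes):
            bp = 3 * (aa_lengths[i] + 1)
            coords.append((cursor, cursor + bp - 1))
            cursor = cursor + bp + int(rng.integers(20, 120))
        # overlap adjustment for conserved pairs
        for i, entry in ctx_plan.items():
            j = entry["partner"]
            if j is not None and entry["overlap"]:
                f_start, f_end = coords[i]
                bp = coords[j][1] - coords[j][0] + 1
                new_start = f_end - 19  # 20 bp intersection
                coords[j] = (new_start, new_start + bp - 1)

        genome_genes = []
        for i in range(n_genes):
            pid = f"{gid}_{i + 1:05d}"
            is_atp, comp, nd = plans[i]
            strand = "+" if rng.random() < 0.5 else "-"
            annotation = ""
            if is_atp:
                annotation = (
                    "composite AAA-family ATPase" if comp else "putative ATPase"
                )
            rec = GeneRecord(
                contig_id=gid,
                gene_id=pid,
                start=coords[i][0],
                end=coords[i][1],
                strand=strand,
                protein_seq=seqs[i],
                annotation=annotation,
            )
            genome_genes.append(rec)
            fasta.append((pid, seqs[i]))
            if is_atp:
                for a, b in spans_per_gene[i]:
                    domain_hits.append(
                        DomainHit(
                            protein_id=pid,
                            accession=f"PF{int(rng.integers(1, 99999)):05d}",
                            name=ATPASE_DOMAIN_NAMES[
                                int(rng.integers(0, len(ATPASE_DOMAIN_NAMES)))
                            ],
                            e_value=_domain_evalue(rng),
                            ali_start=a,
                            ali_end=b,
                        )
                    )
                if comp:
                    if rng.random() < config.unknown_category_fraction:
                        name, category = (
                            UNKNOWN_DOMAIN_NAMES[
                                int(rng.integers(0, len(UNKNOWN_DOMAIN_NAMES)))
                            ],
                            "unknown/DUF",
                        )
                    else:
                        name, category = FUNCTIONAL_DOMAIN_POOL[
                            int(rng.integers(0, len(FUNCTIONAL_DOMAIN_POOL)))
                        ]
                    fa = nd * DOMAIN_BLOCK_AA + 1
                    domain_hits.append(
                        DomainHit(
                            protein_id=pid,
                            accession=f"PF{int(rng.integers(1, 99999)):05d}",
                            name=name,
                            e_value=_domain_evalue(rng),
                            ali_start=fa,
                            ali_end=min(fa + 49, len(seqs[i])),
                        )
                    )
                else:
                    category = None
                atpase_labels[pid] = {
                    "is_atpase": True,
                    "n_atpase_domains": nd,
                    "is_composite": comp,
                    "category": category,
                    "duplicate_of": None,
                    "on_cellular_contig": bool(cellular_flags[g]),
                }
            else:
                n_background += 1
                # occasional decoy hits: non-keyword domains at good e-values
                # and keyword domains above the cutoff
                u = rng.random()
                if u < 0.01:
                    domain_hits.append(
                        DomainHit(pid, "PF00271", "Helicase_C", 1e-10, 1, min(60, aa_lengths[i]))
                    )
                elif u < 0.02:
                    domain_hits.append(
                        DomainHit(pid, "PF13401", "AAA_22", 0.5, 1, min(60, aa_lengths[i]))
                    )

        genes.extend(genome_genes)

        # taxonomy: cellular contigs get strictly >50% cellular best hits
        if cellular_flags[g]:
            n_cell = int(np.ceil(0.7 * n_genes))
            n_cell = max(n_cell, n_genes // 2 + 1)
        else:
            n_cell = n_genes // 5
        cell_idx = set(rng.choice(n_genes, size=min(n_cell, n_genes), replace=False).tolist())
        for i, rec in enumerate(genome_genes):
            if i in cell_idx:
                dom = "bacteria" if rng.random() < 0.7 else "archaea"
            else:
                dom = "mobilome" if rng.random() < 0.6 else "none"
            taxonomy_rows.append((rec.gene_id, gid, dom))

        # neighborhood homology emission
        for i, entry in ctx_plan.items():
            focal = genome_genes[i]
            ctx = entry["type"]
            window = [
                genome_genes[j]
                for j in range(max(0, i - 3), min(n_genes, i + 4))
            ]
            if ctx == "conserved_operon":
                rates = {rec.gene_id: 9.0 for rec in window}
            elif ctx == "conserved_pair":
                partner = genome_genes[entry["partner"]]
                rates = {
                    rec.gene_id: (9.0 if rec.gene_id in (focal.gene_id, partner.gene_id) else 0.3)
                    for rec in window
                }
            else:
                rates = {rec.gene_id: 0.3 for rec in window}
            for rec in window:
                k = int(rng.poisson(rates[rec.gene_id]))
                for _ in range(k):
                    db_counter += 1
                    homology_rows.append(
                        _outfmt6_row(rec.gene_id, f"dbs{db_counter:07d}", 1e-45, 420.0)
                    )
            # above-cutoff noise and a self-hit, to exercise filtering
            db_counter += 1
            homology_rows.append(
                _outfmt6_row(focal.gene_id, f"weak{db_counter:07d}", 1e-5, 60.0)
            )
            homology_rows.append(_outfmt6_row(focal.gene_id, focal.gene_id, 0.0, 999.0))

            context_truth[focal.gene_id] = {
                "type": ctx,
                "partner": (
                    genome_genes[entry["partner"]].gene_id
                    if entry["partner"] is not None
                    else None
                ),
                "overlap": entry["overlap"],
                "family": None,
                "genome": gid,
                "gene_index": i,
            }
            if focal.gene_id in atpase_labels and atpase_labels[focal.gene_id]["is_composite"]:
                composite_genes.append(focal)

    # cross-contig homology: group operon foci into families of ~3 sharing
    # homologs at every offset in consistent order; pair foci into families
    # of 2 sharing homologs at focal and partner only
    by_gene = {rec.gene_id: rec for rec in genes}
    gene_index_on_contig: dict[str, list[GeneRecord]] = {}
    for rec in genes:
        gene_index_on_contig.setdefault(rec.contig_id, []).append(rec)

    def neighbor_at(focal_id: str, offset: int) -> Optional[str]:
        info = context_truth[focal_id]
        contig = gene_index_on_contig[info["genome"]]
        j = info["gene_index"] + offset
        if 0 <= j < len(contig):
            return contig[j].gene_id
        return None

    def link(a: Optional[str], b: Optional[str], evalue: float) -> None:
        if a and b and a != b:
            homology_rows.append(_outfmt6_row(a, b, evalue, 640.0))
            homology_rows.append(_outfmt6_row(b, a, evalue, 640.0))

    # interleave foci by within-genome rank so family members land on
    # different contigs whenever possible (keeps neighborhood windows of one
    # family from sharing genes)
    def interleaved(foci: list[str]) -> list[str]:
        per_genome: dict[str, list[str]] = {}
        for f in foci:
            per_genome.setdefault(context_truth[f]["genome"], []).append(f)
        out = []
        rank = 0
        while True:
            added = False
            for gid in sorted(per_genome):
                if rank < len(per_genome[gid]):
                    out.append(per_genome[gid][rank])
                    added = True
            if not added:
                return out
            rank += 1

    operon_foci = interleaved(
        sorted(f for f, t in context_truth.items() if t["type"] == "conserved_operon")
    )
    for fam, start in enumerate(range(0, len(operon_foci), 3)):
        family = operon_foci[start : start + 3]
        for f in family:
            context_truth[f]["family"] = f"operon{fam:04d}"
        for a, b in zip(family, family[1:]):
            link(a, b, 1e-60)
            for off in (-3, -2, -1, 1, 2, 3):
                link(neighbor_at(a, off), neighbor_at(b, off), 1e-50)

    pair_foci = interleaved(
        sorted(f for f, t in context_truth.items() if t["type"] == "conserved_pair")
    )
    for fam, start in enumerate(range(0, len(pair_foci), 2)):
        family = pair_foci[start : start + 2]
        for f in family:
            context_truth[f]["family"] = f"pair{fam:04d}"
        if len(family) == 2:
            a, b = family
            link(a, b, 1e-60)
            link(context_truth[a]["partner"], context_truth[b]["partner"], 1e-50)

    # duplicate gene calls: exact copies of composite records at identical
    # coordinates under a fresh gene_id
    n_dup = min(config.n_duplicate_candidates, len(composite_genes))
    if n_dup:
        chosen = rng.choice(len(composite_genes), size=n_dup, replace=False)
        for ci in sorted(chosen.tolist()):
            orig = composite_genes[ci]
            dup_id = orig.gene_id + "_dup"
            genes.append(
                GeneRecord(
                    contig_id=orig.contig_id,
                    gene_id=dup_id,
                    start=orig.start,
                    end=orig.end,
                    strand=orig.strand,
                    protein_seq=orig.protein_seq,
                    annotation=orig.annotation,
                )
            )
            fasta.append((dup_id, orig.protein_seq))
            for h in [h for h in domain_hits if h.protein_id == orig.gene_id]:
                domain_hits.append(
                    DomainHit(dup_id, h.accession, h.name, h.e_value, h.ali_start, h.ali_end)
                )
            taxonomy_rows.append((dup_id, orig.contig_id, "none"))
            duplicates[dup_id] = orig.gene_id
            lab = dict(atpase_labels[orig.gene_id])
            lab["duplicate_of"] = orig.gene_id
            atpase_labels[dup_id] = lab

    for g in range(config.n_genomes):
        gid = f"G{g:04d}"
        truth_genomes[gid] = {
            "length_kbp": float(lengths_kbp[g]),
            "planted_atpase_count": planted_counts[g],
            "gc_percent": float(np.clip(rng.normal(39.2, 9.0), 22.0, 64.0)),
            "cellular": bool(cellular_flags[g]),
        }

    paths = SimPaths(
        proteins_fasta=outdir / "proteins.faa",
        gene_table=outdir / "genes.tsv",
        domain_table=outdir / "domains.tsv",
        homology_table=outdir / "homology.tsv",
        taxonomy_table=outdir / "taxonomy.tsv",
        genome_table=outdir / "genomes.tsv",
        truth_json=outdir / "truth.json",
    )
    mio.write_protein_fasta(fasta, paths.proteins_fasta)
    mio.write_gene_table(genes, paths.gene_table)
    mio.write_domain_hits(domain_hits, paths.domain_table)
    mio.write_homology_table(homology_rows, paths.homology_table)
    with open(paths.taxonomy_table, "w") as fh:
        fh.write("protein_id\tcontig_id\tbest_hit_domain\n")
        for pid, contig, dom in taxonomy_rows:
            fh.write(f"{pid}\t{contig}\t{dom}\n")
    with open(paths.genome_table, "w") as fh:
        fh.write("genome_id\tlength_kbp\tgc_percent\n")
        for gid, info in truth_genomes.items():
            fh.write(f"{gid}\t{info['length_kbp']:.3f}\t{info['gc_percent']:.2f}\n")

    truth = SimTruth(
        config=dataclasses.asdict(config),
        genomes=truth_genomes,
        atpase_proteins=atpase_labels,
        context=context_truth,
        duplicates=duplicates,
        n_background=n_background,
    )
    truth.to_json(paths.truth_json)
    return paths, truth
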