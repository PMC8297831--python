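"""Deterministic fixtures reproducing the census's printed worked examples.

These synthetic datasets mirror, at the record level, the arithmetic of the
published composite-protein curation: 1,003 composite candidates of which
441 sit on majority-cellular contigs (excluded, leaving 562), with 57
duplicate gene calls among the survivors (final set 505, of which 311 carry
annotated functional domains and 194 only domains of unknown function), and
the per-category protein/ATPase count table of the mobilome dataset. All
records are synthetic stand-ins; only the counts and filter structure
reproduce the published surfaces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from mobatp import io as mio
from mobatp.records import DomainHit, GeneRecord
from mobatp.simulate import (
    FUNCTIONAL_DOMAIN_POOL,
    UNKNOWN_DOMAIN_NAMES,
    _plant_atpase_protein,
    _random_protein,
)

FIXTURE_NAMES = ("dedup_562", "table2_counts", "curation_1003")

#: mobilome category count table: (category, n_proteins, n_atpases)
TABLE2_COUNTS = [
    ("virus", 44243, 361),
    ("phage", 731372, 2654),
    ("plasmid", 112101, 2216),
    ("other", 35695, 266),
]

_FIXTURE_SEED = 20210708  # fixed: fixtures are deterministic by contract

N_FINAL = 505
N_DUPLICATES = 57
N_CELLULAR = 441
N_UNKNOWN = 194


def _build_curation(outdir: Path, include_cellular: bool) -> dict[str, Path]:
    """Emit the composite-candidate curation fixture.

    One candidate per contig plus background genes; the first 57 retained
    candidates carry an exact duplicate gene call at identical coordinates.
    Retained contigs sit at exactly 50% cellular best hits (kept under the
    strict >50% rule); excluded contigs sit at 60%.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    genes: list[GeneRecord] = []
    fasta: list[tuple[str, str]] = []
    hits: list[DomainHit] = []
    tax_rows: list[tuple[str, str, str]] = []

    # category plan for the 505 distinct retained candidates
    categories: list[tuple[str, str]] = []
    pool = list(FUNCTIONAL_DOMAIN_POOL)
    for i in range(N_FINAL - N_UNKNOWN):
        categories.append(pool[i % len(pool)])
    for i in range(N_UNKNOWN):
        categories.append((UNKNOWN_DOMAIN_NAMES[i % len(UNKNOWN_DOMAIN_NAMES)], "unknown/DUF"))

    def add_contig(
        contig: str, cand_id: str, functional_name: str, cellular: bool, dup: bool
    ) -> None:
        n_bg = 9
        cursor = 1
        records = []
        # background genes
        for b in range(n_bg):
            seq = _random_protein(rng, 80)
            bp = 3 * (len(seq) + 1)
            records.append(
                GeneRecord(contig, f"{contig}_bg{b:02d}", cursor, cursor + bp - 1, "+", seq)
            )
            fasta.append((records[-1].gene_id, seq))
            cursor += bp + 50
        # the composite candidate
        seq, spans = _plant_atpase_protein(rng, 1, composite=True)
        bp = 3 * (len(seq) + 1)
        cand = GeneRecord(
            contig, cand_id, cursor, cursor + bp - 1, "+", seq,
            annotation="composite AAA-family ATPase",
        )
        records.append(cand)
        fasta.append((cand_id, seq))
        a, b = spans[0]
        cand_hits = [
            DomainHit(cand_id, "PF13401", "AAA_22", 1e-20, a, b),
            DomainHit(cand_id, "PF99999", functional_name, 1e-12, b + 1, min(b + 50, len(seq))),
        ]
        hits.extend(cand_hits)
        if dup:
            dup_id = cand_id + "_b"
            records.append(
                GeneRecord(contig, dup_id, cand.start, cand.end, "+", seq,
                           annotation=cand.annotation)
            )
            fasta.append((dup_id, seq))
            for h in cand_hits:
                hits.append(DomainHit(dup_id, h.accession, h.name, h.e_value, h.ali_start, h.ali_end))
        genes.extend(records)
        # taxonomy: exactly 60% cellular on excluded contigs, exactly 50% on
        # retained ones (even protein count), exercising the strict rule
        n = len(records)
        n_cell = int(round(0.6 * n)) if cellular else n // 2
        for i, rec in enumerate(records):
            dom = "bacteria" if i < n_cell else "mobilome"
            tax_rows.append((rec.gene_id, contig, dom))

    for i in range(N_FINAL):
        add_contig(
            f"mc{i:04d}",
            f"mc{i:04d}_cand",
            categories[i][0],
            cellular=False,
            dup=(i < N_DUPLICATES),
        )
    if include_cellular:
        for i in range(N_CELLULAR):
            name, _ = pool[i % len(pool)]
            add_contig(f"cc{i:04d}", f"cc{i:04d}_cand", name, cellular=True, dup=False)

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_table": outdir / "genes.tsv",
        "proteins_fasta": outdir / "proteins.faa",
        "domain_table": outdir / "domains.tsv",
        "taxonomy_table": outdir / "taxonomy.tsv",
    }
    mio.write_gene_table(genes, paths["gene_table"])
    mio.write_protein_fasta(fasta, paths["proteins_fasta"])
    mio.write_domain_hits(hits, paths["domain_table"])
    with open(paths["taxonomy_table"], "w") as fh:
        fh.write("protein_id\tcontig_id\tbest_hit_domain\n")
        for pid, contig, dom in tax_rows:
            fh.write(f"{pid}\t{contig}\t{dom}\n")
    return paths


def make_paper_fixture(name: str, outdir: str | Path) -> dict[str, Path]:
    """Emit a named deterministic fixture under ``outdir``.

    ``dedup_562``: 562 composite candidate records (on contigs that survive
    the cellular exclusion) of which exactly 57 are duplicate gene calls.
    ``curation_1003``: the same plus 441 candidates on majority-cellular
    contigs, i.e. the full pre-exclusion candidate set.
    ``table2_counts``: the per-category protein/ATPase count table.
    Running a fixture twice produces identical files.
    """
    outdir = Path(outdir)
    if name == "dedup_562":
        return _build_curation(outdir, include_cellular=False)
    if name == "curation_1003":
        return _build_curation(outdir, include_cellular=True)
    if name == "table2_counts":
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "categories.tsv"
        with open(path, "w") as fh:
            fh.write("category\tn_proteins\tn_atpases\n")
            for cat, np_, na in TABLE2_COUNTS:
                fh.write(f"{cat}\t{np_}\t{na}\n")
        return {"category_table": path}
    raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
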