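"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: protein/nucleotide FASTA, gene tables (6-column TSV or a
GFF3 dialect), HMMER3 per-domain tables (domtblout) or a generic TSV domain
table, tabular BLAST outfmt6 homology tables and a per-protein taxonomy TSV.
All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from mobatp.records import ContigTaxonomy, DomainHit, GeneRecord, HomologyHit

logger = logging.getLogger("mobatp")

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GENE_TABLE_COLUMNS = ["contig_id", "gene_id", "start", "end", "strand", "annotation"]

DOMAIN_TSV_COLUMNS = ["protein_id", "accession", "name", "e_value", "ali_start", "ali_end"]


def setup_logging(verbose: bool = False) -> None:
    """Log to standard error; -v raises the level to DEBUG."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# FASTA

def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``[(protein_id, sequence), ...]``.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased. A record with an empty sequence is a parse
    error naming the offending line.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(
                f"{path}: record {header!r} at line {header_line} has an "
                "empty sequence"
            )
        entries.append((header, seq.upper()))

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(">"):
                flush(i)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ValueError(f"{path}: empty FASTA header at line {i}")
                header_line = i
                chunks = []
            elif line:
                if header is None:
                    raise ValueError(f"{path}: sequence before header at line {i}")
                chunks.append(line)
        flush(-1)
    return entries


def write_protein_fasta(
    entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for pid, seq in entries:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables

def _genes_from_frame(df: pd.DataFrame, path: Path) -> list[GeneRecord]:
    records = []
    for row in df.itertuples(index=False):
        rec = GeneRecord(
            contig_id=str(row.contig_id),
            gene_id=str(row.gene_id),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            annotation="" if pd.isna(row.annotation) else str(row.annotation),
        )
        rec.validate()
        records.append(rec)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_id] = seen.get(rec.gene_id, 0) + 1
    dupes = sorted(g for g, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate gene_id(s): {dupes}")
    records.sort(key=lambda r: (r.contig_id, r.start, r.end, r.gene_id))
    return records


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(
    path: str | Path, proteins: dict[str, str] | None = None
) -> list[GeneRecord]:
    """Read gene calls from a 6-column TSV or a GFF3 dialect.

    The TSV dialect has a header row with columns
    contig_id, gene_id, start, end, strand, annotation. GFF3 rows use the
    ``ID`` attribute as gene_id and ``product`` (if present) as annotation.
    Records are validated (start <= end, unique gene_id) and returned sorted
    by (contig_id, start). When ``proteins`` (a gene_id -> sequence mapping,
    e.g. from a companion FASTA) is given, sequences are attached.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    is_gff = first.startswith("##gff") or (
        len(first.rstrip("\n").split("\t")) == 9 and not first.startswith("contig_id")
    )
    if is_gff:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}: GFF3 row with {len(parts)} columns")
                attrs = _parse_gff3_attributes(parts[8])
                rows.append(
                    dict(
                        contig_id=parts[0],
                        gene_id=attrs.get("ID", ""),
                        start=parts[3],
                        end=parts[4],
                        strand=parts[6],
                        annotation=attrs.get("product", ""),
                    )
                )
        df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing gene-table columns {sorted(missing)}")
    records = _genes_from_frame(df, path)
    if proteins is not None:
        for rec in records:
            rec.protein_seq = proteins.get(rec.gene_id, "")
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.contig_id, r.gene_id, r.start, r.end, r.strand, r.annotation)
            for r in records
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain hit tables

def read_domain_hits(
    path: str | Path, dialect: str = "tsv"
) -> list[DomainHit]:
    """Read domain annotations from a ``tsv`` or HMMER3 ``domtblout`` table.

    The domtblout dialect is the whitespace-separated per-domain table of
    HMMER 3 (hmmsearch --domtblout): column 1 is the target sequence name,
    column 4 the query (HMM) name, column 5 its accession, column 13 the
    independent e-value and columns 18-19 the alignment coordinates on the
    target. Comment lines (#) are skipped.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    if dialect == "domtblout":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 19:
                    raise ValueError(f"{path}: row {i} has {len(parts)} columns")
                try:
                    hit = DomainHit(
                        protein_id=parts[0],
                        name=parts[3],
                        accession=parts[4],
                        e_value=float(parts[12]),
                        ali_start=int(parts[17]),
                        ali_end=int(parts[18]),
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: row {i}: {exc}") from exc
                hit.validate()
                hits.append(hit)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        missing = set(DOMAIN_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing domain-table columns {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                hit = DomainHit(
                    protein_id=row.protein_id,
                    accession=row.accession,
                    name=row.name,
                    e_value=float(row.e_value),
                    ali_start=int(row.ali_start),
                    ali_end=int(row.ali_end),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
            hit.validate()
            hits.append(hit)
    else:
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    return hits


def write_domain_hits(hits: Sequence[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (h.protein_id, h.accession, h.name, h.e_value, h.ali_start, h.ali_end)
            for h in hits
        ],
        columns=DOMAIN_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Homology (tabular BLAST outfmt6) tables

def read_homology_table(
    path: str | Path, drop_self_hits: bool = True
) -> list[HomologyHit]:
    """Read a 12-column tabular BLAST (outfmt6) file into HomologyHits."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, dtype=str, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        if drop_self_hits and row.qseqid == row.sseqid:
            continue
        hits.append(
            HomologyHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                e_value=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_homology_table(rows: Sequence[tuple], path: str | Path) -> None:
    """Write pre-assembled 12-tuples in outfmt6 column order."""
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Taxonomy tables

def read_taxonomy_table(path: str | Path) -> list[ContigTaxonomy]:
    """Read per-protein best-hit taxonomy and tally per contig.

    Expected columns: protein_id, contig_id, best_hit_domain with the domain
    one of bacteria / archaea / mobilome / none. Bacteria and archaea count
    as cellular best hits.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "contig_id", "best_hit_domain"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {sorted(missing)}")
    out = []
    for contig, grp in df.groupby("contig_id", sort=True):
        cellular = grp["best_hit_domain"].isin(["bacteria", "archaea"]).sum()
        tax = ContigTaxonomy(
            contig_id=str(contig),
            n_proteins=len(grp),
            n_cellular_besthits=int(cellular),
        )
        tax.validate()
        out.append(tax)
    return out


# ---------------------------------------------------------------------------
# Sequence utilities

def translate(nucleotide_seq: str, code: int = 11) -> str:
    """Translate a coding sequence under genetic code 11 or 15.

    Code 15 (used by Lak megaphages) reassigns the TAG stop codon to
    glutamine; code 11 is the standard bacterial table. Translation stops at
    the first remaining stop codon. The input length must be divisible by 3.
    """
    seq = nucleotide_seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in nucleotide sequence: {sorted(bad)}")
    if code not in (11, 15):
        raise ValueError(f"unsupported genetic code {code}")
    return str(Seq(seq).translate(table=code, to_stop=True))


def reverse_complement(nucleotide_seq: str) -> str:
    return str(Seq(nucleotide_seq).reverse_complement())


def translate_gene(nucleotide_seq: str, strand: str, code: int = 11) -> str:
    """Translate a gene region, reverse-complementing minus-strand genes."""
    if strand == "-":
        nucleotide_seq = reverse_complement(nucleotide_seq)
    return translate(nucleotide_seq, code=code)


def gc_content(nucleotide_seq: str) -> float:
    """GC percentage, 100 x (G+C)/(A+C+G+T); N excluded from the denominator."""
    seq = nucleotide_seq.upper()
    if not seq:
        raise ValueError("empty nucleotide sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom
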