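"""Readers and writers for the pipeline's file formats.

Canonical table dialect (loci as rows, individuals as columns):

* SNP genotype CSV — cell codes ``0`` (hom ref), ``1`` (het), ``2``
  (hom alt), ``-`` (missing); first column is the locus id, optional
  last column ``tag`` holds the locus tag sequence.
* Presence/absence CSV — cell codes ``1`` (present), ``0`` (absent),
  ``-`` (missing); same layout.
* Sex CSV — header ``individual_id,sex`` with sex in {M, F, U}.

External alignments are accepted in BLAST tabular (``-outfmt 6``)
column order, and sequences travel as plain FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentHit,
    GenotypeMatrix,
    PACall,
    PAMatrix,
    Reference,
    Sex,
    SnpCall,
)

logger = logging.getLogger(__name__)

_SNP_CODES = {"0": SnpCall.HOM_REF, "1": SnpCall.HET, "2": SnpCall.HOM_ALT,
              "-": SnpCall.MISSING}
_PA_CODES = {"1": PACall.PRESENT, "0": PACall.ABSENT, "-": PACall.MISSING}
_SNP_SYMBOLS = {v: k for k, v in _SNP_CODES.items()}
_PA_SYMBOLS = {v: k for k, v in _PA_CODES.items()}

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# genotype / PA / sex tables
# ---------------------------------------------------------------------------

def read_sex_file(path: str | Path) -> dict[str, Sex]:
    """Read a two-column sex phenotype file (individual_id, sex)."""
    df = pd.read_csv(path, dtype=str)
    expected = ["individual_id", "sex"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"sex file must have header 'individual_id,sex', got {list(df.columns)}"
        )
    out: dict[str, Sex] = {}
    for _, row in df.iterrows():
        ind = str(row["individual_id"])
        if ind in out:
            raise ValueError(f"duplicate individual id in sex file: {ind!r}")
        code = str(row["sex"]).strip().upper()
        try:
            out[ind] = Sex(code)
        except ValueError:
            raise ValueError(
                f"invalid sex code {row['sex']!r} for individual {ind!r} "
                "(expected M, F or U)"
            ) from None
    return out


def _read_marker_table(path, codes, cls, sexes_by_id):
    df = pd.read_csv(path, dtype=str, index_col=0)
    tags = None
    if df.columns.size and df.columns[-1] == "tag":
        tag_col = df.pop("tag")
        tags = [None if pd.isna(t) else str(t) for t in tag_col]
    locus_ids = [str(x) for x in df.index]
    individual_ids = [str(c) for c in df.columns]

    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i, lid in enumerate(locus_ids):
        for j, ind in enumerate(individual_ids):
            raw = values[i, j]
            cell = "" if pd.isna(raw) else str(raw).strip()
            if cell not in codes:
                raise ValueError(
                    f"unparseable cell {raw!r} at locus {lid!r}, "
                    f"individual {ind!r} in {path}"
                )
            calls[i, j] = codes[cell]

    sexes = []
    missing = []
    for ind in individual_ids:
        if ind in sexes_by_id:
            sexes.append(sexes_by_id[ind])
        else:
            sexes.append(Sex.UNKNOWN)
            missing.append(ind)
    if missing:
        logger.warning(
            "%d individual(s) absent from sex file, treated as unknown sex: %s",
            len(missing), ", ".join(missing),
        )
    return cls(locus_ids=locus_ids, individual_ids=individual_ids,
               sexes=sexes, calls=calls, tags=tags)


def read_genotype_tables(
    snp_path: str | Path,
    pa_path: str | Path | None,
    sex_path: str | Path,
) -> tuple[GenotypeMatrix, PAMatrix | None]:
    """Read the SNP table, optional presence/absence table and sex file.

    Individuals keep the order of the SNP table header; individuals not
    listed in the sex file are assigned unknown sex with a logged warning.
    """
    sexes_by_id = read_sex_file(sex_path)
    snp = _read_marker_table(snp_path, _SNP_CODES, GenotypeMatrix, sexes_by_id)
    pa = None
    if pa_path is not None:
        pa = _read_marker_table(pa_path, _PA_CODES, PAMatrix, sexes_by_id)
    return snp, pa


def _write_marker_table(matrix, symbols, path) -> None:
    rows = [[symbols[c] for c in row] for row in matrix.calls]
    df = pd.DataFrame(rows, index=matrix.locus_ids, columns=matrix.individual_ids)
    if matrix.tags is not None:
        df["tag"] = [t if t is not None else "" for t in matrix.tags]
    df.index.name = "locus_id"
    df.to_csv(path)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    _write_marker_table(matrix, _SNP_SYMBOLS, path)


def write_pa_table(matrix: PAMatrix, path: str | Path) -> None:
    _write_marker_table(matrix, _PA_SYMBOLS, path)


def write_sex_file(matrix, path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": matrix.individual_ids,
         "sex": [s.value for s in matrix.sexes]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def read_alignment_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output into alignment hits.

    Strand is inferred from subject coordinate order (sstart > send means
    minus strand) and start/end are normalised so start <= end.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns "
                    f"(outfmt 6), got {len(fields)}"
                )
            qseqid, sseqid, pident, length = fields[0], fields[1], fields[2], fields[3]
            sstart, send = int(fields[8]), int(fields[9])
            strand = "+" if sstart <= send else "-"
            start, end = min(sstart, send), max(sstart, send)
            hits.append(AlignmentHit(
                query_id=qseqid,
                chrom=sseqid,
                start=start,
                end=end,
                strand=strand,
                identity=float(pident) / 100.0,
                aln_length=int(length),
            ))
    return hits


def write_alignment_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in outfmt-6 layout (mismatch/gapopen/evalue fields synthesised)."""
    with open(path, "w") as fh:
        for h in hits:
            mism = round((1.0 - h.identity) * h.aln_length)
            sstart, send = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            fh.write(
                f"{h.query_id}\t{h.chrom}\t{h.identity * 100:.2f}\t{h.aln_length}"
                f"\t{mism}\t0\t1\t{h.aln_length}\t{sstart}\t{send}\t0.0\t0.0\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Reference:
    """Read a FASTA file as a Reference (uppercased, strict A/C/G/T)."""
    chrom_ids: list[str] = []
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGT symbols: {sorted(bad)}"
            )
        chrom_ids.append(rec.id)
        sequences[rec.id] = seq
    return Reference(chrom_ids=chrom_ids, sequences=sequences)


def write_fasta(sequences: Reference | Mapping[str, str], path: str | Path) -> None:
    """Write a Reference or an id->sequence mapping as FASTA."""
    if isinstance(sequences, Reference):
        items = [(cid, sequences.sequences[cid]) for cid in sequences.chrom_ids]
    else:
        items = list(sequences.items())
    records = [SeqRecord(Seq(seq), id=str(name), description="")
               for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------

def write_structure_input(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Export a SNP matrix as a two-row-per-individual STRUCTURE input.

    Alleles are coded 1/2 and missing data as -9: hom ref -> (1,1),
    het -> (1,2), hom alt -> (2,2).  The first line lists locus names.
    """
    first = {SnpCall.HOM_REF: "1", SnpCall.HET: "1",
             SnpCall.HOM_ALT: "2", SnpCall.MISSING: "-9"}
    second = {SnpCall.HOM_REF: "1", SnpCall.HET: "2",
              SnpCall.HOM_ALT: "2", SnpCall.MISSING: "-9"}
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.locus_ids) + "\n")
        for j, ind in enumerate(matrix.individual_ids):
            col = [SnpCall(c) for c in matrix.calls[:, j]]
            fh.write("\t".join([ind] + [first[c] for c in col]) + "\n")
            fh.write("\t".join([ind] + [second[c] for c in col]) + "\n")
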