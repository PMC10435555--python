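"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython (gzip transparently supported by file
name); candidate tables are written as GFF3 plus a TSV mirror with 1-based
inclusive coordinates; calls and frequencies as TSV via pandas.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ltr_scan import ProvirusCandidate


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_reads(path) -> list[tuple[str, str]]:
    """FASTQ or FASTA reads, by extension."""
    p = Path(path)
    stem = p.name[:-3] if p.suffix == ".gz" else p.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    with _open(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def candidates_to_frame(candidates: Iterable[ProvirusCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "locus_id": c.locus_id,
                "contig": c.contig_id,
                "element_start": c.element_span[0] + 1,
                "element_end": c.element_span[1],
                "ltr5_start": c.ltr5_span[0] + 1,
                "ltr5_end": c.ltr5_span[1],
                "ltr3_start": c.ltr3_span[0] + 1,
                "ltr3_end": c.ltr3_span[1],
                "ltr_len": c.ltr_len,
                "ltr_identity": c.ltr_identity,
                "tsd_seq": c.tsd_seq or "",
                "strand": c.strand,
            }
        )
    return pd.DataFrame(rows)


def write_candidates_tsv(candidates: Iterable[ProvirusCandidate], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def write_candidates_gff3(candidates: Iterable[ProvirusCandidate], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates, 1):
            eid = f"ERVi_candidate_{i}"
            base = f"{c.contig_id}\tervi\t"
            fh.write(
                base
                + f"LTR_retrotransposon\t{c.element_span[0] + 1}\t{c.element_span[1]}\t.\t{c.strand}\t.\tID={eid}\n"
            )
            for part, span in (("five_prime", c.ltr5_span), ("three_prime", c.ltr3_span)):
                fh.write(
                    base
                    + f"long_terminal_repeat\t{span[0] + 1}\t{span[1]}\t.\t{c.strand}\t.\tParent={eid};ltr={part}\n"
                )
            if c.tsd_seq:
                t = len(c.tsd_seq)
                fh.write(
                    base
                    + f"target_site_duplication\t{c.element_span[0] + 1 - t}\t{c.element_span[0]}\t.\t{c.strand}\t.\tParent={eid}\n"
                )


def read_candidates_tsv(path) -> list[ProvirusCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str}, keep_default_na=False)
    out = []
    for row in df.itertuples():
        out.append(
            ProvirusCandidate(
                contig_id=str(row.contig),
                ltr5_span=(int(row.ltr5_start) - 1, int(row.ltr5_end)),
                ltr3_span=(int(row.ltr3_start) - 1, int(row.ltr3_end)),
                element_span=(int(row.element_start) - 1, int(row.element_end)),
                tsd_seq=row.tsd_seq or None,
                strand=str(row.strand),
                ltr_identity=float(row.ltr_identity),
            )
        )
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    """TSV with columns sample_id, files, sample_kind, pool_size, group_id."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"sample_id", "files", "sample_kind", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
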