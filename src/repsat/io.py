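"""Plain-text I/O: FASTQ with embedded UMIs, consensus FASTA, FUS tables.

All tables are tab-separated for diff-ability.  FASTQ is Sanger (Phred+33);
the UMI occupies the first ``umi_length`` bases of each record and is echoed
in the header (``UMI=...``) for debuggability, alongside the simulator's
truth clone id (``CLONE=...``) when available.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .repertoire import FUS_COLUMNS, Repertoire
from .synthetic_data import UmiRead

#: Phred score written for UMI bases (qualities are tracked for the
#: biological portion of the read only)
UMI_QUAL = 40


def write_fastq(path, reads: list[UmiRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            header = f"{r.read_id} UMI={r.umi}"
            if r.truth_clone_id is not None:
                header += f" CLONE={r.truth_clone_id}"
            qual = chr(UMI_QUAL + 33) * len(r.umi) + "".join(
                chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{header}\n{r.umi}{r.sequence}\n+\n{qual}\n")


def read_fastq(path, umi_length: int) -> list[UmiRead]:
    """Parse FASTQ, splitting off the first ``umi_length`` bases as the UMI."""
    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            fields = title.split()
            truth = None
            for tok in fields[1:]:
                if tok.startswith("CLONE="):
                    truth = int(tok[6:])
            phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            reads.append(UmiRead(
                read_id=fields[0],
                umi=seq[:umi_length],
                sequence=seq[umi_length:],
                qualities=phred[umi_length:],
                truth_clone_id=truth,
            ))
    return reads


def write_consensus_fasta(path, consensus_reads) -> None:
    """Consensus sequences with UMI and support count in the header."""
    with open(path, "w") as fh:
        for c in consensus_reads:
            header = f"{c.umi};support={c.support}"
            if c.truth_clone_id is not None:
                header += f";clone={c.truth_clone_id}"
            fh.write(f">{header}\n{c.sequence}\n")


def read_consensus_fasta(path):
    from Bio import SeqIO

    from .preprocess import ConsensusRead

    out = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split(";")
        support = 1
        truth = None
        for p in parts[1:]:
            if p.startswith("support="):
                support = int(p[8:])
            elif p.startswith("clone="):
                truth = int(p[6:])
        out.append(ConsensusRead(parts[0], support, str(rec.seq), truth))
    return out


def write_airr(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"productive": str})


def write_fus_table(path, rep: Repertoire) -> None:
    """FUS table with sample metadata in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={rep.sample_id}\n")
        fh.write(f"# depth={rep.depth}\n")
        vol = "" if rep.volume_ml is None else f"{rep.volume_ml:g}"
        fh.write(f"# volume_ml={vol}\n")
        fh.write(f"# arm={rep.arm or ''}\n")
        rep.table.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_fus_table(path) -> Repertoire:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    table = pd.read_csv(path, sep="\t", skiprows=skip)
    if table.empty:
        table = pd.DataFrame(columns=FUS_COLUMNS)
    return Repertoire(
        sample_id=meta.get("sample_id", "sample"),
        depth=int(meta.get("depth", table["read_count"].sum() if len(table) else 0)),
        table=table,
        volume_ml=float(meta["volume_ml"]) if meta.get("volume_ml") else None,
        arm=meta.get("arm") or None,
    )
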