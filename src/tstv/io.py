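"""File-format plumbing: FASTA, BED, VCF, and metadata-stamped TSV/JSON.

Sequence I/O goes through biopython; VCF reading through pysam.  All
tabular outputs carry a commented metadata header (version, seed, config
digest) so that runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


def read_fasta(path) -> dict:
    """Read a FASTA file into an id -> uppercase-sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a 4-column BED (chrom, start, end, name; 0-based half-open)."""
    intervals[["chrom", "start", "end", "amplicon_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Write a minimal VCF 4.2 of biallelic SNVs (chrom, pos, ref, alt)."""
    contigs = list(dict.fromkeys(variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=tstv-{__version__}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def read_vcf_variants(path) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF into (chrom, pos, ref, alt)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos, rec.ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def config_digest(config: dict) -> str:
    """Short stable digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(seed, config: dict) -> str:
    lines = [
        f"# tstv version={__version__}",
        f"# seed={seed}",
        f"# config_digest={config_digest(config)}",
    ]
    return "\n".join(lines) + "\n"


def write_tsv(frame: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write a TSV with a commented metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(metadata_header(seed, config or {}))
        frame.to_csv(fh, sep="\t", index=False)


def write_json(payload: dict, path, seed=None, config: dict | None = None) -> None:
    out = {
        "metadata": {
            "version": __version__,
            "seed": seed,
            "config_digest": config_digest(config or {}),
        },
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
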