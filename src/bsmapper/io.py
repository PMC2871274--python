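"""Plain-text readers and writers for the pipeline's interchange files.

Formats: FASTQ for reads; a TSV mapping table (one row per uniquely
mapped read); a CGmap-like per-site TSV; a truth TSV from the
simulator; optional SAM via pysam. All writers emit deterministic,
byte-stable output.
"""
from __future__ import annotations

import pandas as pd

MAPPING_COLUMNS = [
    "read_id", "strand_code", "chrom", "start", "read_seq",
    "genome_seq", "mismatches_orig", "methylation_string",
]

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_methylated", "n_total"]


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_mapping_tsv(result, path) -> None:
    result.to_dataframe().to_csv(path, sep="\t", index=False)


def read_mapping_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "strand_code": str, "methylation_string": str},
    )
    missing = set(MAPPING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: mapping table missing columns {sorted(missing)}")
    return df


def write_sites_tsv(site_table: pd.DataFrame, path) -> None:
    site_table.to_csv(path, sep="\t", index=False, columns=SITE_COLUMNS)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "form": str, "meth_states": str},
        keep_default_na=False,
    )


def write_unmapped_tsv(result, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in result.unmapped:
            fh.write(f"{read_id}\t{reason}\n")


def write_sam(result, genome, path) -> None:
    """SAM output: mandatory fields plus XF (read form), X3 (3-letter
    mismatches), NM (original-alphabet mismatches), XM (methylation
    string). Reads written in reverse orientation relative to Watson
    (+RC/-FW forms) are stored reverse-complemented with flag 16, as SAM
    requires."""
    import pysam

    from ._dna import revcomp

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": genome.lengths[n]} for n in genome.names],
    }
    tid = {n: i for i, n in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for m in result.mapped:
            a = pysam.AlignedSegment(out.header)
            a.query_name = m.read_id
            reverse = m.form in ("+RC", "-FW")
            a.flag = 16 if reverse else 0
            a.reference_id = tid[m.chrom]
            a.reference_start = m.start - 1
            a.mapping_quality = 255
            a.cigarstring = f"{len(m.read_seq)}M"
            a.query_sequence = revcomp(m.read_seq) if reverse else m.read_seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(m.read_seq))
            a.set_tags([
                ("NM", m.mismatches_orig, "i"),
                ("X3", m.mismatches3, "i"),
                ("XF", m.form, "Z"),
                ("XM", m.methylation_string, "Z"),
            ])
            out.write(a)
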