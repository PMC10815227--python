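"""On-disk formats: catalog FASTA, count/metadata/efflux TSVs, truth sidecar.

The canonical catalog is a mature-sequence FASTA (record ID = miRNA ID)
with an optional companion precursor FASTA keyed by the same IDs, where the
description line carries ``mature_start=<int> mature_end=<int>`` (1-based,
inclusive) locating the mature span; the flanks are recovered from it.
Count tables are TSV with ``sequence`` and ``mirna`` key columns followed
by one integer column per sample.  DNA-alphabet input (T) is transliterated
to U on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .isomir import CanonicalMiRNA, IsomirRecord
from .matrix import CountMatrix
from .simulate import IsomirTemplate, SyntheticTruth

_MATURE_SPAN = re.compile(r"mature_start=(\d+)\s+mature_end=(\d+)")


def write_catalog(
    catalog: Mapping[str, CanonicalMiRNA],
    fasta_path,
    precursor_path=None,
) -> None:
    mature = [
        SeqRecord(Seq(c.mature_seq), id=c.mirna_id, description="")
        for c in catalog.values()
    ]
    SeqIO.write(mature, str(fasta_path), "fasta")
    if precursor_path is not None:
        precursors = []
        for c in catalog.values():
            pre = c.precursor_5p_flank + c.mature_seq + c.precursor_3p_flank
            start = len(c.precursor_5p_flank) + 1
            end = len(c.precursor_5p_flank) + len(c.mature_seq)
            precursors.append(
                SeqRecord(
                    Seq(pre),
                    id=c.mirna_id,
                    description=f"mature_start={start} mature_end={end}",
                )
            )
        SeqIO.write(precursors, str(precursor_path), "fasta")


def load_catalog(fasta_path, precursor_path=None) -> dict[str, CanonicalMiRNA]:
    mature: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        mature[rec.id] = str(rec.seq).upper().replace("T", "U")
    if not mature:
        raise ParseError(f"{fasta_path}: no FASTA records found")
    flanks: dict[str, tuple[str, str]] = {}
    if precursor_path is not None:
        for rec in SeqIO.parse(str(precursor_path), "fasta"):
            m = _MATURE_SPAN.search(rec.description)
            if not m:
                raise ParseError(
                    f"{precursor_path}: record {rec.id} lacks mature_start/mature_end"
                )
            start, end = int(m.group(1)), int(m.group(2))
            pre = str(rec.seq).upper().replace("T", "U")
            if not 1 <= start <= end <= len(pre):
                raise ParseError(f"{precursor_path}: bad mature span for {rec.id}")
            flanks[rec.id] = (pre[: start - 1], pre[end:])
    catalog = {}
    for mid, seq in mature.items():
        f5, f3 = flanks.get(mid, ("", ""))
        catalog[mid] = CanonicalMiRNA(
            mirna_id=mid, mature_seq=seq, precursor_5p_flank=f5, precursor_3p_flank=f3
        )
    return catalog


def write_isomir_table(
    templates: Sequence[IsomirTemplate] | Sequence[IsomirRecord],
    matrix: CountMatrix,
    path,
) -> None:
    """Write an isomiR count TSV (sequence, mirna, one column per sample)."""
    rows = []
    for t in templates:
        fid = getattr(t, "isomir_id")
        counts = matrix.data.loc[fid]
        rows.append({"sequence": t.sequence, "mirna": t.parent, **counts.to_dict()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_samples(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def load_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "score", "ct_mir23a", "ct_mir451a"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_efflux(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False)


def load_efflux(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "replicate_index", "cpm_medium", "cpm_lysate", "is_blank"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def load_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
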