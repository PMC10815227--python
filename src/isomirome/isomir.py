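"""Canonical miRNAs, isomiR sequence variants, and their classification.

An isomiR is any unique small-RNA sequence assigned to a mature miRNA.
Relative to the canonical (database) sequence it may be trimmed or extended
at either end, carry internal substitutions, or combine both.  Classification
places the isomiR on the extended canonical axis (5' precursor flank +
mature sequence + 3' precursor flank) without gaps and annotates:

* ``five_prime_offset`` — positive when the isomiR starts downstream of the
  canonical 5' end (trimmed), negative when extended into the flank;
* ``three_prime_offset`` — positive when extended past the canonical 3' end,
  negative when trimmed;
* internal substitutions (1-based positions on the isomiR itself);
* the variant class: ``canonical``, ``iso_5p``, ``iso_3p``, ``polymorphic``
  (substitutions only) or ``mixed``;
* whether added bases are templated by the precursor flank;
* whether the variant changes the seed — the bases at positions 2–7 of the
  molecule's own 5' end, the primary determinant of target recognition.
  Any 5' shift changes the seed, as does a substitution inside positions 2–7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ClassificationError, InputError, ParseError

RNA_ALPHABET = frozenset("ACGU")
SEED_START, SEED_END = 2, 7  # 1-based, inclusive

#: Default ungapped placement search window: 5' offset and 3' offset bounds.
FIVE_PRIME_BOUNDS = (-2, 4)
THREE_PRIME_BOUNDS = (-4, 4)

VARIANT_CLASSES = ("canonical", "iso_5p", "iso_3p", "polymorphic", "mixed")


def _validate_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise InputError(f"{what} contains non-RNA characters: {bad}")
    return seq


@dataclass(frozen=True)
class CanonicalMiRNA:
    """A mature miRNA reference sequence with optional precursor context."""

    mirna_id: str
    mature_seq: str
    precursor_5p_flank: str = ""
    precursor_3p_flank: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", _validate_rna(self.mature_seq, "mature_seq"))
        object.__setattr__(
            self, "precursor_5p_flank", _validate_rna(self.precursor_5p_flank, "5' flank")
        )
        object.__setattr__(
            self, "precursor_3p_flank", _validate_rna(self.precursor_3p_flank, "3' flank")
        )
        if len(self.mature_seq) < 16:
            raise InputError(
                f"{self.mirna_id}: mature sequence shorter than 16 nt "
                f"({len(self.mature_seq)})"
            )


@dataclass(frozen=True)
class Substitution:
    """A single-nucleotide difference, positioned 1-based on the isomiR."""

    position: int
    canonical: str
    observed: str


@dataclass(frozen=True)
class VariantAnnotation:
    five_prime_offset: int
    three_prime_offset: int
    substitutions: tuple[Substitution, ...]
    variant_class: str
    templated: str  # "templated" | "non_templated" | "unknown"
    seed_changing: bool


@dataclass
class IsomirRecord:
    """A unique isomiR sequence with parent assignment and per-sample counts."""

    isomir_id: str
    sequence: str
    parent: str
    annotation: VariantAnnotation
    counts: Mapping[str, int] = field(default_factory=dict)


def seed_of(sequence: str) -> str:
    """Return the seed: nucleotides at positions 2–7 (1-based) of ``sequence``."""
    sequence = _validate_rna(sequence, "sequence")
    if len(sequence) < SEED_END:
        raise InputError(f"sequence of length {len(sequence)} has no full seed")
    return sequence[SEED_START - 1 : SEED_END]


def _derive_class(o5: int, o3: int, n_subs: int) -> str:
    if o5 == 0 and o3 == 0:
        return "canonical" if n_subs == 0 else "polymorphic"
    if n_subs == 0 and o3 == 0:
        return "iso_5p"
    if n_subs == 0 and o5 == 0:
        return "iso_3p"
    return "mixed"


def classify_isomir(
    sequence: str,
    canonical: CanonicalMiRNA,
    five_prime_bounds: tuple[int, int] = FIVE_PRIME_BOUNDS,
    three_prime_bounds: tuple[int, int] = THREE_PRIME_BOUNDS,
) -> VariantAnnotation:
    """Classify an isomiR sequence against its canonical reference.

    The sequence is slid ungapped along the extended canonical axis.  Among
    placements with 5' offset within ``five_prime_bounds`` and implied 3'
    offset within ``three_prime_bounds``, the winner minimizes the number of
    internal substitutions, then total offset magnitude; remaining ties
    prefer the smaller |5' offset|, then |3' offset|, then fewer seed-window
    substitutions, biasing the call toward the canonical register.

    Bases that fall outside the mature span are extension bases: they are
    compared to the precursor flank to decide templated status and are never
    counted as substitutions.
    """
    seq = _validate_rna(sequence, "isomiR sequence")
    mat = canonical.mature_seq
    if abs(len(seq) - len(mat)) > 5:
        raise ClassificationError(
            f"length difference {len(seq) - len(mat)} vs {canonical.mirna_id} "
            "exceeds the classifiable range"
        )
    f5, f3 = canonical.precursor_5p_flank, canonical.precursor_3p_flank
    ldiff = len(seq) - len(mat)

    best_key: tuple | None = None
    best: tuple[int, int, tuple[Substitution, ...], list[tuple[str, bool | None]]] | None = None
    for o5 in range(five_prime_bounds[0], five_prime_bounds[1] + 1):
        o3 = o5 + ldiff
        if not (three_prime_bounds[0] <= o3 <= three_prime_bounds[1]):
            continue
        subs: list[Substitution] = []
        # extension bases as (side, matches_flank or None when flank missing)
        ext: list[tuple[str, bool | None]] = []
        for i, base in enumerate(seq):
            mpos = o5 + i  # 0-based position on the mature sequence
            if 0 <= mpos < len(mat):
                if base != mat[mpos]:
                    subs.append(Substitution(i + 1, mat[mpos], base))
            elif mpos < 0:
                j = len(f5) + mpos
                ext.append(("5p", f5[j] == base if 0 <= j < len(f5) else None))
            else:
                j = mpos - len(mat)
                ext.append(("3p", f3[j] == base if j < len(f3) else None))
        n_seed = sum(1 for s in subs if SEED_START <= s.position <= SEED_END)
        key = (len(subs), abs(o5) + abs(o3), abs(o5), abs(o3), n_seed)
        if best_key is None or key < best_key:
            best_key = key
            best = (o5, o3, tuple(subs), ext)

    if best is None:
        raise ClassificationError(
            f"no ungapped placement of a {len(seq)} nt sequence on "
            f"{canonical.mirna_id} within the offset bounds"
        )

    o5, o3, subs, ext = best
    if not ext:
        templated = "templated"
    elif any(m is None for _, m in ext):
        templated = "unknown"
    elif all(m for _, m in ext):
        templated = "templated"
    elif any(side == "3p" and m is False for side, m in ext):
        templated = "non_templated"
    else:
        templated = "unknown"

    seed_changing = o5 != 0 or any(SEED_START <= s.position <= SEED_END for s in subs)
    return VariantAnnotation(
        five_prime_offset=o5,
        three_prime_offset=o3,
        substitutions=subs,
        variant_class=_derive_class(o5, o3, len(subs)),
        templated=templated,
        seed_changing=seed_changing,
    )


def feature_id_for(parent: str, sequence: str) -> str:
    """Stable feature identifier for an isomiR row: ``parent|sequence``."""
    return f"{parent}|{sequence}"


def parse_isomir_table(path, catalog: Mapping[str, CanonicalMiRNA]):
    """Parse an isomiR count TSV into records plus a raw count matrix.

    Expected layout (miRGE-style, one row per unique sequence): columns
    ``sequence``, ``mirna`` (parent ID), then one integer column per sample.
    DNA-alphabet sequences are transliterated T→U.  Rows whose parent is
    absent from the catalog go to a rejects table instead of being dropped
    silently.

    Returns ``(records, matrix, rejects)`` where ``matrix`` is a raw
    :class:`~isomirome.matrix.CountMatrix` at isomiR level and ``rejects`` a
    DataFrame of the unassignable rows with a ``reason`` column.
    """
    import pandas as pd

    from .matrix import CountMatrix

    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "mirna": str})
    for col in ("sequence", "mirna"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("sequence", "mirna")]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found")

    records: list[IsomirRecord] = []
    rejects: list[dict] = []
    rows: list[tuple[str, list[int]]] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, counting the header line
        seq_raw, parent = row["sequence"], row["mirna"]
        if not isinstance(seq_raw, str) or not isinstance(parent, str):
            raise ParseError(f"{path}: line {line_no}: malformed sequence/parent fields")
        counts = []
        for c in sample_cols:
            v = row[c]
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ParseError(f"{path}: line {line_no}: non-integer count {v!r}") from None
            if float(v) != iv:
                raise ParseError(f"{path}: line {line_no}: non-integer count {v!r}")
            if iv < 0:
                raise InputError(f"line {line_no}: negative count {iv}")
            counts.append(iv)
        if parent not in catalog:
            rejects.append(
                {"sequence": seq_raw, "mirna": parent, "reason": "unknown parent miRNA"}
            )
            continue
        seq = _validate_rna(seq_raw, f"line {line_no} sequence")
        annotation = classify_isomir(seq, catalog[parent])
        fid = feature_id_for(parent, seq)
        records.append(
            IsomirRecord(
                isomir_id=fid,
                sequence=seq,
                parent=parent,
                annotation=annotation,
                counts=dict(zip(sample_cols, counts)),
            )
        )
        rows.append((fid, counts))

    data = pd.DataFrame(
        [c for _, c in rows],
        index=pd.Index([f for f, _ in rows], name="feature_id"),
        columns=sample_cols,
        dtype="int64",
    )
    matrix = CountMatrix(data, level="isomir", normalized=False)
    rejects_df = pd.DataFrame(rejects, columns=["sequence", "mirna", "reason"])
    return records, matrix, rejects_df


def parent_map(records: Iterable[IsomirRecord]) -> dict[str, str]:
    """feature_id → parent miRNA ID for a set of records."""
    return {r.isomir_id: r.parent for r in records}


def seed_changing_ids(records: Iterable[IsomirRecord]) -> set[str]:
    return {r.isomir_id for r in records if r.annotation.seed_changing}
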