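"""Alignment containers, FASTA/PHYLIP I/O, column profiling and assembly screening.

The central object is :class:`Alignment`, an immutable taxa-by-columns DNA
character matrix.  Characters are stored as small integer codes so that the
downstream per-site statistics (observed variability, pairwise distances)
vectorize over columns.  The alphabet is the determinate bases ``A C G T``,
the gap ``-``, the mask symbols ``N`` and ``?`` (equivalent; a masked base is
a position suppressed at assembly time for insufficient read support), and
the remaining IUPAC ambiguity codes, which are retained verbatim but treated
as indeterminate in pairwise comparisons.

Column coordinates are 0-based and half-open throughout the API; 1-based
coordinates appear only in human-readable error messages and reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "ColumnAnnotation",
    "ColumnProfile",
    "ScreenResult",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "read_annotation",
    "write_annotation",
    "profile_columns",
    "screen_assemblies",
    "slice_columns",
    "CATEGORIES",
]

# character -> code. Determinate bases first so that `code < 4` tests work.
_ALPHABET = "ACGT-N" + "RYSWKMBDHV"
CHAR_TO_CODE = {c: i for i, c in enumerate(_ALPHABET)}
CHAR_TO_CODE["?"] = CHAR_TO_CODE["N"]  # '?' and 'N' are equivalent masks
CODE_TO_CHAR = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)

GAP_CODE = CHAR_TO_CODE["-"]
MASK_CODE = CHAR_TO_CODE["N"]
N_DETERMINATE = 4  # codes 0..3 are A,C,G,T

# IUPAC code -> set of compatible bases, used when likelihood models
# marginalize partial states.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT",
}

CATEGORIES = ("noncoding", "exon", "intron", "tRNA", "rRNA", "unassigned")


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad characters, duplicate labels)."""


def _encode_row(label: str, seq: str) -> np.ndarray:
    raw = seq.upper()
    codes = np.empty(len(raw), dtype=np.uint8)
    for i, ch in enumerate(raw):
        code = CHAR_TO_CODE.get(ch)
        if code is None:
            raise AlignmentError(
                f"illegal character {ch!r} in sequence {label!r} at column {i + 1} (1-based)"
            )
        codes[i] = code
    return codes


@dataclass(frozen=True)
class Alignment:
    """Taxa-by-columns character matrix over the DNA alphabet.

    Attributes
    ----------
    taxa : tuple of str
        Unique, non-empty sequence labels, in input order.
    codes : ndarray of uint8, shape (n_taxa, n_cols)
        Integer-encoded characters (see module docstring).
    """

    taxa: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            seen: set[str] = set()
            dup = next(t for t in self.taxa if t in seen or seen.add(t))
            raise AlignmentError(f"duplicate taxon label {dup!r}")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon label")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxon list")
        self.codes.setflags(write=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return int(self.codes.shape[1])

    @classmethod
    def from_sequences(cls, items: Iterable[tuple[str, str]]) -> "Alignment":
        """Build from ``(label, sequence)`` pairs, validating shape and alphabet."""
        labels: list[str] = []
        rows: list[np.ndarray] = []
        for label, seq in items:
            labels.append(label)
            rows.append(_encode_row(label, str(seq)))
        if not labels:
            raise AlignmentError("alignment contains no sequences")
        width = len(rows[0])
        for label, row in zip(labels, rows):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: sequence {label!r} has length {len(row)}, "
                    f"expected {width} (from {labels[0]!r})"
                )
        return cls(tuple(labels), np.vstack(rows) if width else
                   np.empty((len(labels), 0), dtype=np.uint8))

    def sequence(self, taxon: str | int) -> str:
        i = taxon if isinstance(taxon, int) else self.taxa.index(taxon)
        return CODE_TO_CHAR[self.codes[i]].tobytes().decode()

    def select_taxa(self, keep: Sequence[str]) -> "Alignment":
        """Restrict to ``keep`` (alignment order preserved); columns unchanged."""
        keep_set = set(keep)
        missing = keep_set - set(self.taxa)
        if missing:
            raise AlignmentError(f"unknown taxa: {sorted(missing)}")
        idx = [i for i, t in enumerate(self.taxa) if t in keep_set]
        return Alignment(tuple(self.taxa[i] for i in idx), self.codes[idx].copy())


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or (relaxed, sequential or interleaved) PHYLIP alignment.

    ``?`` and ``N`` are both read as the mask state; characters are
    normalized to upper case.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        return Alignment.from_sequences((r.id, str(r.seq)) for r in records)
    if format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise AlignmentError(f"cannot parse PHYLIP file {path}: {exc}") from exc
        return Alignment.from_sequences((r.id, str(r.seq)) for r in msa)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=t, description="")
        for i, t in enumerate(aln.taxa)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


@dataclass(frozen=True)
class ColumnAnnotation:
    """Per-column functional category (and optional locus name).

    ``categories`` holds one label per column from the closed vocabulary
    ``noncoding / exon / intron / tRNA / rRNA / unassigned``; ``loci`` holds
    a locus name (e.g. ``ycf1``) or ``""`` where none applies.
    """

    categories: np.ndarray  # dtype object/str, len n_cols
    loci: np.ndarray        # dtype object/str, len n_cols

    def __post_init__(self) -> None:
        bad = set(np.unique(self.categories)) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown annotation categories: {sorted(bad)}")
        if len(self.categories) != len(self.loci):
            raise ValueError("categories and loci lengths differ")

    @property
    def n_cols(self) -> int:
        return len(self.categories)

    @classmethod
    def blank(cls, n_cols: int) -> "ColumnAnnotation":
        return cls(
            np.full(n_cols, "unassigned", dtype=object),
            np.full(n_cols, "", dtype=object),
        )


def read_annotation(path, n_cols: int) -> ColumnAnnotation:
    """Read a BED-like annotation: ``start<TAB>end<TAB>category[<TAB>locus]``.

    Intervals are 0-based, half-open. Later lines overwrite earlier ones.
    """
    ann = ColumnAnnotation.blank(n_cols)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
            start, end, category = int(parts[0]), int(parts[1]), parts[2]
            locus = parts[3] if len(parts) > 3 else ""
            if category not in CATEGORIES:
                raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
            if not (0 <= start <= end <= n_cols):
                raise ValueError(f"{path}:{lineno}: interval [{start},{end}) out of range")
            ann.categories[start:end] = category
            ann.loci[start:end] = locus
    return ann


def write_annotation(ann: ColumnAnnotation, path) -> None:
    """Write the annotation back as merged BED-like intervals."""
    with open(path, "w") as fh:
        n = ann.n_cols
        i = 0
        while i < n:
            j = i
            while (
                j + 1 < n
                and ann.categories[j + 1] == ann.categories[i]
                and ann.loci[j + 1] == ann.loci[i]
            ):
                j += 1
            fields = [str(i), str(j + 1), str(ann.categories[i])]
            if ann.loci[i]:
                fields.append(str(ann.loci[i]))
            fh.write("\t".join(fields) + "\n")
            i = j + 1


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column character-class counts and pattern identity.

    ``mask_counts`` counts mask symbols together with non-N IUPAC ambiguity
    codes (all indeterminate for pairwise comparisons), so that
    ``gap + mask + determinate == n_taxa`` at every column.  Pattern ids are
    assigned only to columns with at least one determinate base (mirroring
    how ML programs count "alignment patterns"); all-indeterminate columns
    get pattern id -1.
    """

    gap_counts: np.ndarray
    mask_counts: np.ndarray
    determinate_counts: np.ndarray
    all_indeterminate: np.ndarray  # bool
    pattern_ids: np.ndarray        # int, -1 for all-indeterminate columns
    n_patterns: int

    @property
    def n_all_indeterminate(self) -> int:
        return int(self.all_indeterminate.sum())


def profile_columns(aln: Alignment) -> ColumnProfile:
    """Classify characters per column and count distinct column patterns."""
    codes = aln.codes
    gap = (codes == GAP_CODE).sum(axis=0)
    det = (codes < N_DETERMINATE).sum(axis=0)
    mask = aln.n_taxa - gap - det
    all_ind = det == 0
    pattern_ids = np.full(aln.n_cols, -1, dtype=np.int64)
    informative = ~all_ind
    n_patterns = 0
    if informative.any():
        _, ids = np.unique(codes[:, informative], axis=1, return_inverse=True)
        pattern_ids[informative] = ids
        n_patterns = int(ids.max()) + 1
    return ColumnProfile(gap, mask, det, all_ind, pattern_ids, n_patterns)


@dataclass(frozen=True)
class ScreenResult:
    kept: tuple[str, ...]
    discarded: dict[str, str] = field(default_factory=dict)  # taxon -> reason


def screen_assemblies(
    completeness: Mapping[str, float],
    ref_distances: Mapping[str, float],
    group_distances: Sequence[float],
) -> ScreenResult:
    """Apply the assembly quality screens: completeness and reference distance.

    A taxon is discarded if its estimated completeness is below 0.80, or if
    its pairwise distance to the subsectional assembly reference exceeds
    twice the standard deviation of all such distances within the subsection
    (``group_distances``, sample SD).
    """
    for t, c in completeness.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"completeness for {t!r} outside [0,1]: {c}")
    if len(group_distances) < 2:
        raise ValueError(
            "group_distances has fewer than 2 members; the SD is undefined — "
            "skip the distance criterion for single-member groups"
        )
    sd = float(np.std(np.asarray(group_distances, dtype=float), ddof=1))
    kept: list[str] = []
    discarded: dict[str, str] = {}
    for taxon in completeness:
        c = completeness[taxon]
        d = ref_distances.get(taxon)
        if c < 0.80:
            discarded[taxon] = f"incomplete (completeness {c:.3f} < 0.80)"
        elif d is not None and d > 2.0 * sd:
            discarded[taxon] = f"divergent (distance {d:.4g} > 2*SD {2 * sd:.4g})"
        else:
            kept.append(taxon)
    return ScreenResult(tuple(kept), discarded)


def slice_columns(aln: Alignment, cols: Iterable[int]) -> Alignment:
    """New alignment keeping ``cols`` (sorted ascending); taxa unchanged.

    An empty selection yields a 0-column alignment.
    """
    idx = np.asarray(sorted(set(int(c) for c in cols)), dtype=np.int64)
    if idx.size and (idx[0] < 0 or idx[-1] >= aln.n_cols):
        bad = idx[0] if idx[0] < 0 else idx[-1]
        raise IndexError(f"column index {bad} out of range [0, {aln.n_cols})")
    return Alignment(aln.taxa, aln.codes[:, idx].copy())


def profile_report(aln: Alignment, profile: ColumnProfile | None = None) -> str:
    """Tab-separated per-column profile report (1-based columns for humans)."""
    profile = profile or profile_columns(aln)
    out = io.StringIO()
    out.write("column\tgaps\tmasked\tdeterminate\tall_indeterminate\tpattern\n")
    for c in range(aln.n_cols):
        out.write(
            f"{c + 1}\t{profile.gap_counts[c]}\t{profile.mask_counts[c]}\t"
            f"{profile.determinate_counts[c]}\t"
            f"{int(profile.all_indeterminate[c])}\t{profile.pattern_ids[c]}\n"
        )
    return out.getvalue()
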