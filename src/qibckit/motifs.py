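"""Non-overlapping degenerate DNA motif counting and genome scanning.

A motif is a string over {A, C, G, T, N}; N in the *motif* matches any of
A/C/G/T, while N in the *sequence* (assembly-masked base) matches nothing.
Counting is a greedy left-to-right scan — on a match, advance by the motif
length, otherwise by one — which, for fixed-length motifs, yields the
maximum number of mutually non-overlapping occurrences.

Occurrence density is reported as ``100 * count / sequence_length`` (per
strand). Reverse-complement scans are reported as separate records and are
never merged into the forward density.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ValidationError

_MOTIF_ALPHABET = set("ACGTN")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")
_SEQ_ALPHABET_BYTES = np.frombuffer(b"ACGTN", dtype="S1")


@dataclass(frozen=True)
class Motif:
    """A validated degenerate motif (only N among IUPAC ambiguity codes)."""

    pattern: str

    @property
    def length(self) -> int:
        return len(self.pattern)


def compile_motif(pattern: str) -> Motif:
    """Validate and normalise a motif string (case-folded to upper).

    Rejects empty patterns and any character outside {A, C, G, T, N} —
    including other IUPAC codes, which are refused loudly rather than
    silently mis-matched.
    """
    if not pattern:
        raise ValidationError("motif pattern must be non-empty")
    upper = pattern.upper()
    for ch in upper:
        if ch not in _MOTIF_ALPHABET:
            raise ValidationError(
                f"unsupported motif character {ch!r}: only A, C, G, T and N "
                "are accepted"
            )
    return Motif(upper)


def _as_byte_array(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    if arr.size and not np.isin(arr, _SEQ_ALPHABET_BYTES).all():
        bad = sorted(
            {b.decode() for b in np.unique(arr[~np.isin(arr, _SEQ_ALPHABET_BYTES)])}
        )
        raise ValidationError(f"sequence contains non-ACGTN characters: {bad}")
    return arr


def find_occurrences(sequence: str, motif: Motif) -> np.ndarray:
    """All (possibly overlapping) 0-based match start positions."""
    arr = _as_byte_array(sequence)
    n = arr.size
    L = motif.length
    if n < L:
        return np.zeros(0, dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for j, ch in enumerate(motif.pattern):
        column = arr[j : n - L + 1 + j]
        if ch == "N":
            ok &= np.isin(column, _BASE_BYTES)  # sequence N matches nothing
        else:
            ok &= column == ch.encode("ascii")
    return np.flatnonzero(ok).astype(np.int64)


def count_nonoverlapping(sequence: str, motif: Motif) -> int:
    """Greedy non-overlapping occurrence count (optimal for fixed length)."""
    count = 0
    next_free = 0
    for start in find_occurrences(sequence, motif):
        if start >= next_free:
            count += 1
            next_free = start + motif.length
    return count


def motif_density(count: int, sequence_length: int) -> float:
    """Occurrence density as a percentage of sequence positions."""
    if sequence_length < 1:
        raise ValidationError("sequence_length must be >= 1")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return 100.0 * count / sequence_length


@dataclass(frozen=True)
class MotifCount:
    """Per-sequence non-overlapping count and density.

    ``sequence_length`` counts every position; ``effective_length`` counts
    non-N positions only. ``density_percent`` uses ``sequence_length``;
    ``density_percent_effective`` is the non-N variant.
    """

    sequence_id: str
    sequence_length: int
    effective_length: int
    count: int

    @property
    def density_percent(self) -> float:
        return motif_density(self.count, self.sequence_length)

    @property
    def density_percent_effective(self) -> float:
        if self.effective_length == 0:
            return 0.0
        return motif_density(self.count, self.effective_length)


@dataclass(frozen=True)
class GenomeScanReport:
    """Aggregate of per-record motif counts over a FASTA scan.

    Aggregates cover the forward-strand records only; reverse-complement
    records (ids suffixed ``|revcomp``) are listed but never merged.
    """

    motif: Motif
    records: tuple[MotifCount, ...]
    revcomp: bool = False

    @property
    def forward_records(self) -> tuple[MotifCount, ...]:
        return tuple(r for r in self.records if not r.sequence_id.endswith("|revcomp"))

    @property
    def aggregate_count(self) -> int:
        return sum(r.count for r in self.forward_records)

    @property
    def aggregate_length(self) -> int:
        return sum(r.sequence_length for r in self.forward_records)

    @property
    def aggregate_effective_length(self) -> int:
        return sum(r.effective_length for r in self.forward_records)

    @property
    def aggregate_density_percent(self) -> float:
        return motif_density(self.aggregate_count, self.aggregate_length)

    @property
    def aggregate_density_percent_effective(self) -> float:
        return motif_density(self.aggregate_count, self.aggregate_effective_length)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "sequence_id\tlength\teffective_length\tcount\t"
                "density_percent\tdensity_percent_effective\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.sequence_id}\t{r.sequence_length}\t{r.effective_length}\t"
                    f"{r.count}\t{r.density_percent:.6f}\t"
                    f"{r.density_percent_effective:.6f}\n"
                )

    def to_json(self, path) -> None:
        payload = {
            "motif": self.motif.pattern,
            "revcomp": self.revcomp,
            "n_records": len(self.forward_records),
            "aggregate_count": self.aggregate_count,
            "aggregate_length": self.aggregate_length,
            "aggregate_effective_length": self.aggregate_effective_length,
            "aggregate_density_percent": self.aggregate_density_percent,
            "aggregate_density_percent_effective": self.aggregate_density_percent_effective,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _iter_fasta(path: Path) -> Iterator:
    if str(path).endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fasta")
    else:
        yield from SeqIO.parse(str(path), "fasta")


def count_record(sequence_id: str, sequence: str, motif: Motif) -> MotifCount:
    seq = sequence.upper()
    return MotifCount(
        sequence_id=sequence_id,
        sequence_length=len(seq),
        effective_length=len(seq) - seq.count("N"),
        count=count_nonoverlapping(seq, motif),
    )


def scan_fasta(
    path,
    motif: Motif,
    record_filter: str | None = None,
    revcomp: bool = False,
) -> GenomeScanReport:
    """Scan a (possibly gzipped) FASTA file for non-overlapping motif hits.

    ``record_filter`` is a regular expression matched (``re.search``)
    against record ids, e.g. ``r"chr([1-9]|1[0-9]|2[0-2])$"`` for human
    autosomes. With ``revcomp``, each record's reverse complement is scanned
    and reported as an extra row with id suffix ``|revcomp``.
    Raises :class:`ValidationError` for unreadable files or empty selections.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"FASTA file not found: {path}")
    pattern = re.compile(record_filter) if record_filter else None

    records: list[MotifCount] = []
    for rec in _iter_fasta(path):
        if pattern and not pattern.search(rec.id):
            continue
        seq = str(rec.seq)
        records.append(count_record(rec.id, seq, motif))
        if revcomp:
            rc = str(Seq(seq).reverse_complement())
            records.append(count_record(f"{rec.id}|revcomp", rc, motif))
    if not records:
        raise ValidationError(
            f"no records selected from {path}"
            + (f" with filter {record_filter!r}" if record_filter else "")
        )
    return GenomeScanReport(motif=motif, records=tuple(records), revcomp=revcomp)


def expected_iid_density(
    motif: Motif, base_probs: dict[str, float]
) -> tuple[float, float]:
    """Analytic densities (percent) for an i.i.d. sequence.

    Returns ``(per_position, greedy)``: the per-position match probability
    (product of per-column base probabilities, N columns summing all four)
    and its renewal-theory correction ``p / (1 + p (L - 1))`` for the greedy
    non-overlapping count, both x100. The greedy value is a first-order
    approximation that ignores self-overlap correlation.
    """
    p = 1.0
    for ch in motif.pattern:
        if ch == "N":
            p *= sum(base_probs.get(b, 0.0) for b in "ACGT")
        else:
            p *= base_probs.get(ch, 0.0)
    greedy = p / (1.0 + p * (motif.length - 1))
    return 100.0 * p, 100.0 * greedy
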