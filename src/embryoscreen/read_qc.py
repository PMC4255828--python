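"""Quality trimming and filtering of sequencing reads.

Trimming follows the modified Mott algorithm: each base contributes a score
``limit - p_err`` where ``p_err = 10**(-Q/10)`` is the Phred error
probability, and the retained region is the contiguous segment with the
maximum score sum (Kadane's algorithm). Bases in low-quality runs score
negative and are dropped from the ends; a read whose every segment scores
<= 0 is discarded entirely. After trimming, reads are filtered on ambiguous
base count and minimum length.

Defaults match the preprocessing the downstream quantification assumes:
error-probability limit 0.05, at most 2 ambiguous bases, minimum length 50.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_LIMIT = 0.05
DEFAULT_MAX_AMBIGUOUS = 2
DEFAULT_MIN_LEN = 50


@dataclass
class PhredRead:
    """A read with per-base Phred quality scores."""

    id: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValidationError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "PhredRead":
        return PhredRead(self.id, self.bases[start:end], self.qualities[start:end])


def error_probability(q: float) -> float:
    """Phred score -> base-call error probability, p = 10**(-Q/10)."""
    return 10.0 ** (-q / 10.0)


def mott_trim(read: PhredRead, limit: float = DEFAULT_LIMIT) -> tuple[int, int]:
    """Retained interval (0-based, half-open) under modified Mott trimming.

    Maximises sum(limit - p_err) over contiguous segments. Ties are broken
    leftmost first, then longest, so the result is deterministic. Returns
    (0, 0) when no segment scores > 0 (including the empty read).
    """
    if not 0.0 < limit < 1.0:
        raise ValidationError(f"limit must be in (0, 1), got {limit}")
    best_score = 0.0
    best = (0, 0)
    cur_sum = 0.0
    cur_start = 0
    for i, q in enumerate(read.qualities):
        cur_sum += limit - error_probability(q)
        if cur_sum > best_score or (
            cur_sum == best_score
            and best_score > 0.0
            and (cur_start < best[0] or (cur_start == best[0] and i + 1 > best[1]))
        ):
            best_score = cur_sum
            best = (cur_start, i + 1)
        if cur_sum < 0.0:
            cur_sum = 0.0
            cur_start = i + 1
    return best


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: Optional[str] = None  # 'ambiguity' | 'length' when discarded


def filter_read(
    read: PhredRead,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LEN,
) -> FilterDecision:
    """Post-trim filter: discard on >max_ambiguous N bases or short length."""
    n_count = read.bases.upper().count("N")
    if n_count > max_ambiguous:
        return FilterDecision(False, "ambiguity")
    if len(read) < min_len:
        return FilterDecision(False, "length")
    return FilterDecision(True)


def trim_and_filter(
    read: PhredRead,
    limit: float = DEFAULT_LIMIT,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[Optional[PhredRead], int]:
    """Apply trim then filter; returns (kept read or None, bases removed)."""
    start, end = mott_trim(read, limit)
    trimmed = read.slice(start, end)
    removed = len(read) - len(trimmed)
    decision = filter_read(trimmed, max_ambiguous, min_len)
    return (trimmed if decision.keep else None), removed


# ---------------------------------------------------------------------------
# FASTQ streaming


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


_FASTQ_FORMATS = {"phred33": "fastq", "phred64": "fastq-illumina"}


def _records(handle: IO[str], encoding: str) -> Iterator[PhredRead]:
    fmt = _FASTQ_FORMATS[encoding]
    it = SeqIO.parse(handle, fmt)
    n = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ record #{n + 1}: {exc}") from exc
        n += 1
        yield PhredRead(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])


def _write_read(handle: IO[str], read: PhredRead, encoding: str) -> None:
    rec = SeqRecord(id=read.id, description="", seq=None)
    from Bio.Seq import Seq

    rec.seq = Seq(read.bases)
    rec.letter_annotations["phred_quality"] = read.qualities
    SeqIO.write(rec, handle, _FASTQ_FORMATS[encoding])


@dataclass
class TrimSummary:
    reads_in: int = 0
    reads_kept: int = 0
    bases_removed: int = 0
    discarded_ambiguity: int = 0
    discarded_length: int = 0
    broken_pairs: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def process_fastq(
    in_path: str | Path,
    out_path: str | Path,
    limit: float = DEFAULT_LIMIT,
    max_ambiguous: int = DEFAULT_MAX_AMBIGUOUS,
    min_len: int = DEFAULT_MIN_LEN,
    in2_path: str | Path | None = None,
    out2_path: str | Path | None = None,
    broken_path: str | Path | None = None,
    encoding: str = "phred33",
) -> TrimSummary:
    """Trim+filter a FASTQ stream (optionally paired) to output files.

    ``bases_removed`` counts bases trimmed from every input read, whether or
    not the read survives the subsequent filter. In paired mode a pair is
    emitted only when both mates survive; orphaned mates go to
    ``broken_path`` when given, otherwise they are dropped (and counted in
    ``broken_pairs`` either way).
    """
    if encoding not in _FASTQ_FORMATS:
        raise ValidationError(f"unknown FASTQ encoding {encoding!r}")
    summary = TrimSummary()

    def _process_one(read: PhredRead) -> tuple[Optional[PhredRead], Optional[str]]:
        start, end = mott_trim(read, limit)
        trimmed = read.slice(start, end)
        summary.reads_in += 1
        summary.bases_removed += len(read) - len(trimmed)
        decision = filter_read(trimmed, max_ambiguous, min_len)
        if not decision.keep:
            if decision.reason == "ambiguity":
                summary.discarded_ambiguity += 1
            else:
                summary.discarded_length += 1
            return None, decision.reason
        return trimmed, None

    if in2_path is None:
        with _open_text(in_path, "r") as ih, _open_text(out_path, "w") as oh:
            for read in _records(ih, encoding):
                kept, _ = _process_one(read)
                if kept is not None:
                    summary.reads_kept += 1
                    _write_read(oh, kept, encoding)
        return summary

    if out2_path is None:
        raise ValidationError("paired input requires out2_path")
    broken_handle = _open_text(broken_path, "w") if broken_path else None
    try:
        with _open_text(in_path, "r") as ih1, _open_text(in2_path, "r") as ih2, \
                _open_text(out_path, "w") as oh1, _open_text(out2_path, "w") as oh2:
            it1, it2 = _records(ih1, encoding), _records(ih2, encoding)
            for r1 in it1:
                try:
                    r2 = next(it2)
                except StopIteration:
                    raise FormatError("paired FASTQ files have unequal record counts")
                k1, _ = _process_one(r1)
                k2, _ = _process_one(r2)
                if k1 is not None and k2 is not None:
                    summary.reads_kept += 2
                    _write_read(oh1, k1, encoding)
                    _write_read(oh2, k2, encoding)
                elif k1 is not None or k2 is not None:
                    summary.broken_pairs += 1
                    orphan = k1 if k1 is not None else k2
                    if broken_handle is not None:
                        summary.reads_kept += 1
                        _write_read(broken_handle, orphan, encoding)
            try:
                next(it2)
            except StopIteration:
                pass
            else:
                raise FormatError("paired FASTQ files have unequal record counts")
    finally:
        if broken_handle is not None:
            broken_handle.close()
    return summary


def write_fastq(reads: Iterable[PhredRead], path: str | Path, encoding: str = "phred33") -> None:
    """Write reads to a (optionally gzipped) FASTQ file."""
    with _open_text(path, "w") as handle:
        for read in reads:
            _write_read(handle, read, encoding)
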