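"""Read quality control for MethylRAD libraries.

Two filters are applied before site assignment: reads whose mean per-base
Phred score falls below 30 are removed, and reads in which more than 8% of
bases are N are removed. For paired input a pair is dropped whenever either
mate fails — the signature fragments are short, so an unreliable mate
invalidates the observation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["Read", "QCReport", "passes_quality", "passes_n_content", "filter_fastq"]

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33
DEFAULT_MIN_PHRED = 30.0
DEFAULT_MAX_N_FRAC = 0.08


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, one per base

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    @classmethod
    def from_fastq_record(cls, title: str, seq: str, qual: str) -> "Read":
        return cls(
            read_id=title.split()[0] if title else "",
            sequence=seq.upper(),
            qualities=tuple(ord(c) - PHRED_OFFSET for c in qual),
        )


@dataclass
class QCReport:
    """Exact bookkeeping of a filtering run (units = reads, or pairs for PE)."""

    records_in: int = 0
    records_kept: int = 0
    fail_quality: int = 0
    fail_n_content: int = 0
    paired: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def records_dropped(self) -> int:
        return self.records_in - self.records_kept

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in ("records_in", "records_kept", "fail_quality", "fail_n_content"):
                fh.write(f"{k}\t{getattr(self, k)}\n")
            fh.write(f"records_dropped\t{self.records_dropped}\n")
            fh.write(f"paired\t{int(self.paired)}\n")


def passes_quality(read: Read, min_phred: float = DEFAULT_MIN_PHRED) -> bool:
    """True iff the read's mean per-base Phred score is >= *min_phred*."""
    if not read.qualities:
        logger.warning("read %s is empty; failing quality filter", read.read_id)
        return False
    return sum(read.qualities) / len(read.qualities) >= min_phred


def passes_n_content(read: Read, max_n_frac: float = DEFAULT_MAX_N_FRAC) -> bool:
    """True iff the fraction of N bases is <= *max_n_frac*."""
    if not read.sequence:
        return True
    return read.sequence.count("N") / len(read.sequence) <= max_n_frac


def _passes(read: Read, min_phred: float, max_n_frac: float) -> tuple[bool, str]:
    if not passes_quality(read, min_phred):
        return False, "quality"
    if not passes_n_content(read, max_n_frac):
        return False, "n_content"
    return True, ""


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_records(path: str | Path):
    rec_no = 0
    with _open(path) as fh:
        try:
            for rec_no, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), 1):
                yield Read.from_fastq_record(title, seq, qual)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near record {rec_no + 1} in {path}: {exc}") from exc


def _write_record(fh, read: Read) -> None:
    qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
    fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def filter_fastq(
    in1: str | Path,
    out1: str | Path,
    in2: str | Path | None = None,
    out2: str | Path | None = None,
    min_phred: float = DEFAULT_MIN_PHRED,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
) -> QCReport:
    """Filter a FASTQ file (or pair) and return the exact QC report.

    For paired input the unit of the report is the pair and both mates are
    dropped if either fails; the failure reason recorded is the first
    failing rule of the first failing mate.
    """
    report = QCReport(paired=in2 is not None)
    if in2 is None:
        with _open(out1, "wt") as oh:
            for read in _fastq_records(in1):
                report.records_in += 1
                ok, reason = _passes(read, min_phred, max_n_frac)
                if ok:
                    report.records_kept += 1
                    _write_record(oh, read)
                elif reason == "quality":
                    report.fail_quality += 1
                else:
                    report.fail_n_content += 1
        return report

    if out2 is None:
        raise ValueError("paired input requires out2")
    it1, it2 = _fastq_records(in1), _fastq_records(in2)
    with _open(out1, "wt") as oh1, _open(out2, "wt") as oh2:
        for r1, r2 in zip(it1, it2, strict=True):
            report.records_in += 1
            ok1, reason1 = _passes(r1, min_phred, max_n_frac)
            ok2, reason2 = _passes(r2, min_phred, max_n_frac)
            if ok1 and ok2:
                report.records_kept += 1
                _write_record(oh1, r1)
                _write_record(oh2, r2)
            else:
                reason = reason1 if not ok1 else reason2
                if reason == "quality":
                    report.fail_quality += 1
                else:
                    report.fail_n_content += 1
    return report
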