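"""Read quality control: restriction-residual filtering and fixed-length trimming.

Genuine single-end RAD reads begin with the enzyme-specific restriction
residual (``TGCAGG`` for SbfI). Reads lacking the exact residual are
sequencing artefacts or contaminants and are discarded; surviving reads are
trimmed to a fixed length so that every locus stack compares identical
coordinates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_RESIDUAL = "TGCAGG"
DEFAULT_TRIM_LEN = 70


@dataclass
class RawRead:
    """One unaligned read: identifier, bases over {A,C,G,T,N}, per-base qualities."""

    read_id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and qualities "
                f"({len(self.quals)}) differ in length"
            )


def filter_and_trim_reads(
    reads: Iterable[RawRead],
    residual: str = DEFAULT_RESIDUAL,
    trim_len: int = DEFAULT_TRIM_LEN,
    stats: dict | None = None,
) -> Iterator[RawRead]:
    """Keep reads starting with the exact residual and trim them to ``trim_len``.

    Matching is case-insensitive (bases are uppercased first). Reads shorter
    than ``trim_len`` are dropped. Relative order is preserved. If ``stats``
    is given, the counters ``reads_in``, ``reads_kept`` and ``reads_dropped``
    are incremented in place.
    """
    if trim_len < len(residual):
        raise ValueError("trim_len must be at least as long as the residual")
    residual = residual.upper()
    for read in reads:
        if stats is not None:
            stats["reads_in"] = stats.get("reads_in", 0) + 1
        bases = read.bases.upper()
        if len(bases) >= trim_len and bases.startswith(residual):
            if stats is not None:
                stats["reads_kept"] = stats.get("reads_kept", 0) + 1
            yield RawRead(read.read_id, bases[:trim_len], read.quals[:trim_len])
        else:
            if stats is not None:
                stats["reads_dropped"] = stats.get("reads_dropped", 0) + 1


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file (plain or gzip) as :class:`RawRead` records.

    Malformed records raise ``ValueError`` carrying the record index.
    """
    with _open_text(path) as handle:
        index = -1
        try:
            for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                yield RawRead(title.split()[0], seq, qual)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index + 1}: {exc}") from exc


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    """Write reads to FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{read.quals}\n")
            n += 1
    return n


def qc_fastq(
    in_path: str | Path,
    out_path: str | Path,
    residual: str = DEFAULT_RESIDUAL,
    trim_len: int = DEFAULT_TRIM_LEN,
) -> dict:
    """Filter+trim one FASTQ file to another; returns the QC counters."""
    stats: dict = {"reads_in": 0, "reads_kept": 0, "reads_dropped": 0}
    write_fastq(filter_and_trim_reads(read_fastq(in_path), residual, trim_len, stats), out_path)
    return stats
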