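"""Enrichment scoring of two-pool phage-display count tables.

Biopanning yields two sequenced pools per variant library: phages bound
non-specifically (N.S. pool) and phages eluted from the immobilized
target.  A variant's binding score is the ratio of its read frequency in
the eluted pool to its frequency in the N.S. pool.  Strong binders are
enriched by selection (score >= 5, positive class); variants depleted
relative to background (score < 1) are the negative class.  The band
between the two thresholds carries no label and is dropped from training.

Frequencies are computed from the full-table read totals *before* the
minimum-read filter is applied, so the score of a record does not depend
on which other records survive filtering.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import validate_sequence

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence", "count_eluted", "count_ns")


@dataclass
class CountRecord:
    """One library variant with per-pool read counts and derived scores."""

    sequence: str
    count_eluted: int
    count_ns: int
    freq_eluted: float = math.nan
    freq_ns: float = math.nan
    score: float = math.nan  # inf = eluted-only; nan = absent from both pools


@dataclass
class TrainingSplit:
    """One subsampled training set: every positive plus one negative subset."""

    positives: list[str]
    negatives: list[str]

    @property
    def sequences(self) -> list[str]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives)), np.zeros(len(self.negatives))]
        )


@dataclass
class LabeledDataset:
    """Binary-labeled sequences plus the k subsampled training splits."""

    positives: list[str]
    negatives: list[str]
    splits: list[TrainingSplit] = field(default_factory=list)
    seed: int | None = None


def enrichment_score(freq_eluted: float, freq_ns: float) -> float:
    """Ratio of eluted-pool to N.S.-pool frequency.

    Returns ``inf`` when the variant is present only in the eluted pool
    (unbounded enrichment, treated downstream as positive) and ``nan``
    when it is absent from both pools (undefined; excluded from labeling).
    """
    if freq_eluted < 0 or freq_ns < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_ns == 0:
        return math.inf if freq_eluted > 0 else math.nan
    return freq_eluted / freq_ns


def load_count_table(path: str | Path, format: str | None = None) -> list[CountRecord]:
    """Load a two-pool count table (CSV or TSV) and compute pool frequencies.

    Columns ``sequence``, ``count_eluted``, ``count_ns`` are required.
    Counts must be pre-aggregated: a duplicated sequence is an error.
    Frequencies are normalized by the full-table per-pool totals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    if format is None:
        format = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if format not in {"csv", "tsv"}:
        raise ValueError(f"unsupported format {format!r}")
    delimiter = "\t" if format == "tsv" else ","

    records: list[CountRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None or any(
            col not in reader.fieldnames for col in REQUIRED_COLUMNS
        ):
            raise ValueError(
                f"{path}: header must contain columns {', '.join(REQUIRED_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                seq = row["sequence"].strip()
                validate_sequence(seq)
                eluted = _parse_count(row["count_eluted"])
                ns = _parse_count(row["count_ns"])
            except (ValueError, AttributeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if seq in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate sequence {seq!r}; "
                    "counts must be pre-aggregated"
                )
            seen.add(seq)
            records.append(CountRecord(seq, eluted, ns))

    total_eluted = sum(r.count_eluted for r in records)
    total_ns = sum(r.count_ns for r in records)
    for rec in records:
        rec.freq_eluted = rec.count_eluted / total_eluted if total_eluted else 0.0
        rec.freq_ns = rec.count_ns / total_ns if total_ns else 0.0
        rec.score = enrichment_score(rec.freq_eluted, rec.freq_ns)
    return records


def _parse_count(raw: str) -> int:
    value = int(raw)
    if value < 0:
        raise ValueError(f"negative count {value}")
    return value


def read_filter(records: list[CountRecord], min_reads: int = 3) -> list[CountRecord]:
    """Retain records with more than *min_reads* reads in either pool.

    The threshold is strict (``count > min_reads``); frequencies are not
    recomputed after filtering.
    """
    return [
        r for r in records if r.count_eluted > min_reads or r.count_ns > min_reads
    ]


def label(
    records: list[CountRecord],
    pos_threshold: float = 5.0,
    neg_threshold: float = 1.0,
) -> LabeledDataset:
    """Assign binary binding labels from enrichment scores.

    score >= *pos_threshold* -> positive; score < *neg_threshold* ->
    negative; the intermediate band and undefined (nan) scores are
    dropped (the counts of dropped records are logged).
    """
    positives, negatives = [], []
    n_mid = n_undefined = 0
    for rec in records:
        if math.isnan(rec.score):
            n_undefined += 1
        elif rec.score >= pos_threshold:
            positives.append(rec.sequence)
        elif rec.score < neg_threshold:
            negatives.append(rec.sequence)
        else:
            n_mid += 1
    logger.info(
        "label: %d positive, %d negative, %d mid-band dropped, %d undefined dropped",
        len(positives), len(negatives), n_mid, n_undefined,
    )
    return LabeledDataset(positives=positives, negatives=negatives)


def split_negatives(dataset: LabeledDataset, k: int = 5, seed: int = 0) -> LabeledDataset:
    """Partition the negatives into k near-equal subsets; pair each with all positives.

    The partition is a seeded uniform shuffle followed by contiguous
    slicing, so subset sizes differ by at most one and the result is
    deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(dataset.negatives):
        raise ValueError(
            f"cannot split {len(dataset.negatives)} negatives into {k} subsets"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.negatives))
    shuffled = [dataset.negatives[i] for i in order]
    base, extra = divmod(len(shuffled), k)
    splits, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        subset = shuffled[start : start + size]
        start += size
        splits.append(TrainingSplit(positives=list(dataset.positives), negatives=subset))
    return LabeledDataset(
        positives=dataset.positives,
        negatives=dataset.negatives,
        splits=splits,
        seed=seed,
    )


def write_fasta(sequences: list[str], path: str | Path, prefix: str = "seq") -> None:
    """Write sequences as FASTA with ids ``<prefix>_<i>``."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=f"{prefix}_{i}", description="")
        for i, s in enumerate(sequences)
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[str]:
    from Bio.SeqIO import parse

    return [str(rec.seq) for rec in parse(str(path), "fasta")]
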