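"""Post-denoising quality control for ESV tables.

Four stages, applied in a fixed order:

1. :func:`msa_frameshift_filter` — remove sequences that cannot be placed in
   an end-gap-only alignment against the modal-length block.  COI is protein
   coding, so genuine amplicons of one primer set should align without
   internal gaps; a sequence needing a leading/internal gap or leaving
   unaligned trailing bases is a putative pseudogene or PCR/sequencing
   artifact.
2. :func:`filter_min_total_reads` — drop ESVs with < 100 reads overall.
3. :func:`filter_replicate_min` — zero any sample-replicate cell with < 5
   reads (guards against tag switching between samples).
4. :func:`pool_replicates` — pool replicates per sample and convert to
   presence/absence.

The chain is idempotent and each stage only ever removes signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .core_io import EsvRecord, PresenceMatrix

__all__ = [
    "FilterLog",
    "msa_frameshift_filter",
    "filter_min_total_reads",
    "filter_replicate_min",
    "pool_replicates",
    "run_filter_chain",
]

MIN_TOTAL_READS = 100
MIN_REPLICATE_READS = 5


@dataclass
class FilterLog:
    """Per-ESV removal reasons: frameshift | low_total | empty_after_replicate_filter."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def add(self, esv_id: str, reason: str) -> None:
        self.removed.append((esv_id, reason))


def _aligns_end_gap_only(seq: str, modal_len: int) -> bool:
    # With internal gaps forbidden, a multiple alignment of same-primer
    # amplicons degenerates to block placement: a sequence fits iff it has
    # exactly the modal length (shorter -> leading/trailing gap; longer ->
    # unaligned overhang).
    return len(seq) == modal_len


def msa_frameshift_filter(
    records: Sequence[EsvRecord], log: FilterLog | None = None
) -> list[EsvRecord]:
    """Keep only sequences of the modal length of the input.

    Mirrors alignment-based length/frameshift filtering with the gap-opening
    penalty set prohibitively high: gaps can only appear at sequence ends, so
    any sequence whose length differs from the aligned block is removed as a
    putative indel/frameshift artifact.  The modal length is computed on the
    raw input; ties break toward the longer length.
    """
    if not records:
        return []
    amplicons = {r.amplicon for r in records}
    if len(amplicons) > 1:
        raise ValueError(f"records span multiple amplicons: {sorted(amplicons)}")
    lengths = Counter(len(r.sequence) for r in records)
    top = max(lengths.values())
    modal_len = max(length for length, cnt in lengths.items() if cnt == top)
    retained = []
    for r in records:
        if _aligns_end_gap_only(r.sequence, modal_len):
            retained.append(r)
        elif log is not None:
            log.add(r.esv_id, "frameshift")
    return retained


def filter_min_total_reads(
    records: Sequence[EsvRecord],
    min_total: int = MIN_TOTAL_READS,
    log: FilterLog | None = None,
) -> list[EsvRecord]:
    """Drop ESVs whose read total over all sample x replicate cells is < min_total."""
    retained = []
    for r in records:
        if r.total_reads >= min_total:
            retained.append(r)
        elif log is not None:
            log.add(r.esv_id, "low_total")
    return retained


def filter_replicate_min(
    records: Sequence[EsvRecord], min_reads: int = MIN_REPLICATE_READS
) -> list[EsvRecord]:
    """Zero every sample-replicate cell holding fewer than min_reads reads."""
    out = []
    for r in records:
        counts = {k: v for k, v in r.counts.items() if v >= min_reads}
        out.append(replace(r, counts=counts))
    return out


def pool_replicates(
    records: Sequence[EsvRecord],
    samples: Sequence[str] | None = None,
    log: FilterLog | None = None,
) -> PresenceMatrix:
    """Pool replicates per sample and convert to presence/absence.

    An ESV is present in a sample iff any replicate retains reads.  Feature
    columns that end up absent everywhere are dropped; all requested samples
    are kept as rows even if empty (they stay aligned with metadata).
    """
    if samples is None:
        sample_set = sorted({s for r in records for (s, _) in r.counts})
    else:
        sample_set = list(samples)
    data = {}
    for r in records:
        present = pd.Series(False, index=sample_set)
        for (sample, _rep), reads in r.counts.items():
            if reads > 0 and sample in present.index:
                present[sample] = True
        if present.any():
            data[r.esv_id] = present
        elif log is not None:
            log.add(r.esv_id, "empty_after_replicate_filter")
    df = pd.DataFrame(data, index=sample_set, dtype=bool)
    return PresenceMatrix(df)


def run_filter_chain(
    records: Sequence[EsvRecord],
    min_total: int = MIN_TOTAL_READS,
    min_replicate: int = MIN_REPLICATE_READS,
    samples: Sequence[str] | None = None,
    log: FilterLog | None = None,
) -> tuple[list[EsvRecord], PresenceMatrix]:
    """Apply the full QC chain in its fixed order; returns records + presence."""
    kept = msa_frameshift_filter(records, log=log)
    kept = filter_min_total_reads(kept, min_total=min_total, log=log)
    kept = filter_replicate_min(kept, min_reads=min_replicate)
    presence = pool_replicates(kept, samples=samples, log=log)
    kept = [r for r in kept if r.esv_id in set(presence.features)]
    return kept, presence
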