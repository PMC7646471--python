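"""Recurrence tallying, head/tail threshold and APOBEC motif annotation.

A hotspot is an identical SNV (chrom, pos, ref, alt) recurring in at
least ``t`` samples, where ``t`` is the smallest integer for which the
count distribution's tail beyond ``t`` outweighs the mass at ``t``.
APOBEC-type candidates are the hotspots whose pyrimidine-strand change
is C>G or C>T in a TCN trinucleotide context.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CohortTable, SnvRecord, revcomp

MutationKey = tuple[str, int, str, str]


class NoThresholdError(ValueError):
    """No integer satisfies the head/tail ratio rule."""


@dataclass
class RecurrenceEntry:
    count: int
    gene: str
    protein_change: str | None
    samples: tuple[str, ...]


@dataclass
class RecurrenceTable:
    entries: dict[MutationKey, RecurrenceEntry]

    def counts(self) -> list[int]:
        return [e.count for e in self.entries.values()]


@dataclass
class HotspotEntry:
    key: MutationKey
    count: int
    gene: str
    protein_change: str | None
    motif_class: str  # APOBEC_TCN | other
    subclass: str  # YTCN | RTCN | NA
    samples: tuple[str, ...] = ()
    apobec_associated: bool | None = None
    association_p: float | None = None
    association_fdr: float | None = None


@dataclass
class HotspotPanel:
    threshold: int
    hotspots: list[HotspotEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hotspots)

    @property
    def candidates(self) -> list[HotspotEntry]:
        """Hotspots in an APOBEC-type motif (candidate APOBEC hotspots)."""
        return [h for h in self.hotspots if h.motif_class == "APOBEC_TCN"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hotspots:
            chrom, pos, ref, alt = h.key
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": h.gene,
                    "protein_change": h.protein_change or "",
                    "count": h.count,
                    "motif_class": h.motif_class,
                    "subclass": h.subclass,
                    "apobec_associated": h.apobec_associated,
                    "association_p": h.association_p,
                    "association_fdr": h.association_fdr,
                }
            )
        return pd.DataFrame(rows)


def tally_recurrence(cohort: CohortTable) -> RecurrenceTable:
    """Count carriers of every distinct mutation key in the cohort."""
    by_key: dict[MutationKey, list[SnvRecord]] = {}
    for rec in cohort.records:
        by_key.setdefault(rec.key, []).append(rec)
    entries = {}
    for key, recs in by_key.items():
        entries[key] = RecurrenceEntry(
            count=len({r.sample_id for r in recs}),
            gene=recs[0].gene,
            protein_change=recs[0].protein_change,
            samples=tuple(sorted({r.sample_id for r in recs})),
        )
    return RecurrenceTable(entries=entries)


def find_recurrence_threshold(counts) -> int:
    """Smallest t with N(count > t) / N(count = t) > 1.

    ``counts`` is the multiset of per-mutation carrier counts.  A zero
    denominator with a positive numerator counts as satisfied (gappy
    tails keep the smallest-integer semantics).  Raises
    :class:`NoThresholdError` when no t in 1..max(counts) qualifies.
    """
    counts = list(counts)
    if not counts:
        raise NoThresholdError("empty count multiset")
    tab = Counter(counts)
    cmax = max(tab)
    above = len(counts)
    for t in range(1, cmax + 1):
        at_t = tab.get(t, 0)
        above -= at_t
        if above > 0 and (at_t == 0 or above / at_t > 1):
            return t
    raise NoThresholdError("no integer satisfies the head/tail ratio rule")


def annotate_apobec_motif(window: str, ref: str, alt: str) -> tuple[str, str]:
    """Classify a mutation's motif on the pyrimidine strand.

    ``window`` is a plus-strand sequence of odd length >= 3 centred on
    the mutated base.  The change is APOBEC-type iff, after conversion
    to the strand carrying the pyrimidine, it reads TC>TG or TC>TT
    (C>G / C>T in a TCN context).  The subclass inspects the base 5' of
    the T: C/T gives YTCN, A/G gives RTCN; it is NA when the window is
    too short (or ambiguous) or for non-APOBEC changes.
    """
    window = window.upper()
    if len(window) < 3 or len(window) % 2 == 0:
        raise ValueError("window must have odd length >= 3")
    centre = len(window) // 2
    if window[centre] != ref.upper():
        raise ValueError(
            f"window centre {window[centre]} does not match ref {ref}"
        )
    if ref.upper() in ("G", "A"):
        window = revcomp(window)
        alt = revcomp(alt.upper())
        ref = revcomp(ref.upper())
    else:
        alt = alt.upper()
        ref = ref.upper()
    if ref != "C" or alt not in ("G", "T"):
        return ("other", "NA")
    if window[centre - 1] != "T":
        return ("other", "NA")
    # APOBEC-type; subclass needs the -2 base
    if centre < 2:
        return ("APOBEC_TCN", "NA")
    minus2 = window[centre - 2]
    if minus2 in ("C", "T"):
        return ("APOBEC_TCN", "YTCN")
    if minus2 in ("A", "G"):
        return ("APOBEC_TCN", "RTCN")
    return ("APOBEC_TCN", "NA")


def call_hotspots(cohort: CohortTable, threshold: int | None = None) -> HotspotPanel:
    """Call the cohort's hotspot panel and annotate APOBEC motifs.

    The recurrence threshold is derived from the cohort's own count
    distribution unless given.  Ordering is deterministic: descending
    count, then genomic key.
    """
    if not cohort.records:
        raise ValueError("empty cohort")
    table = tally_recurrence(cohort)
    if threshold is None:
        threshold = find_recurrence_threshold(table.counts())
    context_by_key: dict[MutationKey, str | None] = {}
    for rec in cohort.records:
        ctx = rec.central_context(2)
        if ctx is not None and context_by_key.get(rec.key) is None:
            context_by_key[rec.key] = ctx

    hotspots = []
    for key, entry in table.entries.items():
        if entry.count < threshold:
            continue
        chrom, pos, ref, alt = key
        ctx = context_by_key.get(key)
        if ctx is not None:
            motif_class, subclass = annotate_apobec_motif(ctx, ref, alt)
        else:
            motif_class, subclass = ("other", "NA")
        hotspots.append(
            HotspotEntry(
                key=key,
                count=entry.count,
                gene=entry.gene,
                protein_change=entry.protein_change,
                motif_class=motif_class,
                subclass=subclass,
                samples=entry.samples,
            )
        )
    hotspots.sort(key=lambda h: (-h.count, h.key))
    return HotspotPanel(threshold=threshold, hotspots=hotspots)
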