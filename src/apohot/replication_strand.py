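"""Lagging-strand-template scoring of cytosine mutations from RFD tracks.

APOBEC deaminates cytosines in single-stranded DNA, which is most
exposed on the lagging-strand template.  For each C/G mutation we ask
whether the strand carrying the mutated cytosine (Watson if ref is C,
Crick if ref is G) is replicated mostly as a lagging-strand template in
a given cell line: positive RFD marks Watson-lagging regions, negative
RFD Crick-lagging ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import RfdTrack, SnvRecord


@dataclass
class LaggingProfile:
    key: tuple
    indicators: dict[str, int | None]  # per cell line: 1, -1 or None

    @property
    def lagging_probability(self) -> float | None:
        vals = [v for v in self.indicators.values() if v is not None]
        if not vals:
            return None
        return float(np.mean([(v + 1) / 2 for v in vals]))

    @property
    def n_covered(self) -> int:
        return sum(v is not None for v in self.indicators.values())


def lagging_indicator(record: SnvRecord, track: RfdTrack) -> int | None:
    """1 when the mutated cytosine's strand is the lagging-strand template.

    Returns None (missing) for non-C/G references, uncovered positions
    and RFD exactly 0 (no strand preference information).
    """
    if record.ref not in ("C", "G"):
        return None
    v = track.value_at(record.chrom, record.pos)
    if v is None or v == 0:
        return None
    watson_lagging = v > 0
    cytosine_on_watson = record.ref == "C"
    return 1 if watson_lagging == cytosine_on_watson else -1


def lagging_profile(record: SnvRecord, tracks: list[RfdTrack]) -> LaggingProfile:
    """Per-cell-line indicators and their summary probability."""
    indicators = {t.cell_line: lagging_indicator(record, t) for t in tracks}
    return LaggingProfile(key=record.key, indicators=indicators)


def compare_lagging(probabilities_a, probabilities_b) -> dict:
    """Replicative-asymmetry tests on two groups of lagging probabilities.

    (i) two-sided Wilcoxon rank-sum between the groups (APOBEC-associated
    vs other hotspots), and (ii) one-sided signed-rank of each group's
    probabilities against 0.5 ('greater': preferential lagging-strand
    placement).
    """
    a = np.asarray(list(probabilities_a), dtype=float)
    b = np.asarray(list(probabilities_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")

    def _vs_half(x):
        d = x - 0.5
        if np.allclose(d, 0):
            return float("nan"), 1.0
        w, p = stats.wilcoxon(d, alternative="greater", zero_method="wilcox")
        return float(w), float(p)

    w_a, p_a = _vs_half(a)
    w_b, p_b = _vs_half(b)
    return {
        "ranksum_stat": float(u_stat),
        "ranksum_p": float(u_p),
        "signedrank_a_stat": w_a,
        "signedrank_a_p": p_a,
        "signedrank_b_stat": w_b,
        "signedrank_b_p": p_b,
    }
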