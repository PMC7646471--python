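"""Minimum-free-energy DNA hairpin prediction for mutation-centred windows.

A Zuker-style dynamic programme over unimolecular, non-pseudoknotted
structures without multiloops: every helix is a single chain of nested
pairs closed by a terminal (hairpin) loop; side-by-side hairpins are
allowed in the exterior.  Energies are nearest-neighbour DNA stack free
energies at 37 degC plus hairpin/bulge/internal-loop initiation
penalties (editable TSV tables under ``data/``).  Absolute free
energies are a surrogate for full folding servers; downstream analysis
relies on ordering and thresholding of the values, not on equality with
any particular folder.

The centre of a window is "in loop" when it is unpaired and lies
strictly inside the innermost (hairpin-closing) pair of a stem; bulge
and internal-loop positions do not count as in-loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("apohot")

_DATA_DIR = Path(__file__).parent / "data"

MIN_HAIRPIN_LOOP = 3  # minimum unpaired bases in a terminal loop
MAX_BULGE = 8  # maximum bulge loop size considered
MAX_INTERNAL = 10  # maximum total unpaired bases in an internal loop
MIN_LEN = 13
MAX_LEN = 31

#: thermal energy at 310.15 K, kcal/mol (Jacobson-Stockmayer extrapolation)
_RT = 0.6163
_JS_COEFF = 1.75

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
#: crude fixed stack value for steps involving a G.T wobble pair (the
#: wobble model is an approximation, off by default)
_WOBBLE_STACK = -1.0


@lru_cache(maxsize=1)
def _load_tables():
    stacks = pd.read_csv(_DATA_DIR / "nn_stacks_dna.tsv", sep="\t")
    stack_map = dict(zip(stacks["step"], stacks["dg37"].astype(float)))
    loops = pd.read_csv(_DATA_DIR / "loop_penalties_dna.tsv", sep="\t")
    loop_map = {}
    for loop_type, grp in loops.groupby("loop_type"):
        grp = grp.sort_values("size")
        loop_map[loop_type] = (
            grp["size"].to_numpy(dtype=float),
            grp["dg37"].to_numpy(dtype=float),
        )
    return stack_map, loop_map


class EnergyModel:
    """Nearest-neighbour DNA energies with loop initiation penalties."""

    def __init__(self, allow_gt_wobble: bool = False):
        self.allow_gt_wobble = allow_gt_wobble
        self._stacks, self._loops = _load_tables()

    def pairable(self, x: str, y: str) -> bool:
        if (x, y) in _WC:
            return True
        return self.allow_gt_wobble and (x, y) in _WOBBLE

    def loop_penalty(self, loop_type: str, size: int) -> float:
        sizes, dgs = self._loops[loop_type]
        if size <= sizes[-1]:
            return float(np.interp(size, sizes, dgs))
        return float(dgs[-1] + _JS_COEFF * _RT * np.log(size / sizes[-1]))

    def stack(self, top: str) -> float:
        """Stack free energy keyed by the 5'->3' top-strand dinucleotide."""
        return self._stacks[top]

    def transition(self, seq: str, i: int, j: int, k: int, l: int) -> float:
        """Energy of going from closing pair (i,j) to inner pair (k,l)."""
        d1, d2 = k - i - 1, j - l - 1
        wob = self.allow_gt_wobble and (
            (seq[i], seq[j]) in _WOBBLE or (seq[k], seq[l]) in _WOBBLE
        )
        if d1 == 0 and d2 == 0:
            return _WOBBLE_STACK if wob else self.stack(seq[i] + seq[k])
        if d1 == 0 or d2 == 0:
            size = d1 + d2
            e = self.loop_penalty("bulge", size)
            if size == 1:  # closing pairs still stack across a 1-nt bulge
                e += _WOBBLE_STACK if wob else self.stack(seq[i] + seq[k])
            return e
        return self.loop_penalty("internal", d1 + d2)

    def admissible(self, i: int, j: int, k: int, l: int) -> bool:
        d1, d2 = k - i - 1, j - l - 1
        if d1 < 0 or d2 < 0 or l - k - 1 < MIN_HAIRPIN_LOOP:
            return False
        if d1 == 0 and d2 == 0:
            return True
        if d1 == 0 or d2 == 0:
            return d1 + d2 <= MAX_BULGE
        return d1 + d2 <= MAX_INTERNAL


@dataclass
class FoldResult:
    """An MFE structure for one window.

    ``pairing[p]`` is the 1-based partner of position p (0 = unpaired).
    ``loop_closing_pair`` holds 0-based indices of the innermost pair of
    the terminal loop containing the centre, when the centre is in one.
    """

    sequence: str
    pairing: tuple[int, ...]
    delta_g: float
    centre_in_loop: bool
    loop_closing_pair: tuple[int, int] | None = None

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            sorted(
                (p, q - 1)
                for p, q in enumerate(self.pairing)
                if q and p < q - 1
            )
        )

    @property
    def is_empty(self) -> bool:
        return not any(self.pairing)


@dataclass
class LoopFeature:
    key: tuple
    delta_g: float
    in_loop: bool
    normalised_score: float = 1.0


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must contain only A/C/G/T")
    if not (MIN_LEN <= len(seq) <= MAX_LEN):
        raise ValueError(f"sequence length must be in [{MIN_LEN}, {MAX_LEN}]")
    return seq


def chain_energy(seq: str, chain: tuple[tuple[int, int], ...], model: EnergyModel) -> float:
    """Free energy of a single nested chain of pairs (outermost first)."""
    e = 0.0
    for (i, j), (k, l) in zip(chain, chain[1:]):
        e += model.transition(seq, i, j, k, l)
    ii, jj = chain[-1]
    e += model.loop_penalty("hairpin", jj - ii - 1)
    return e


def energy_of_structure(seq: str, pairs, model: EnergyModel) -> float:
    """Total energy of a set of pairs forming disjoint hairpin chains."""
    pairs = sorted(pairs)
    total = 0.0
    used = set()
    for p in pairs:
        if p in used:
            continue
        # p opens a new chain: collect all pairs nested inside it
        chain = [q for q in pairs if p[0] <= q[0] and q[1] <= p[1]]
        chain.sort()
        used.update(chain)
        total += chain_energy(seq, tuple(chain), model)
    return total


def _fill_v(seq: str, model: EnergyModel):
    """DP over chain-closed structures: V[(i,j)] = best energy closed by (i,j)."""
    n = len(seq)
    V: dict[tuple[int, int], float] = {}
    choice: dict[tuple[int, int], tuple[int, int] | None] = {}
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not model.pairable(seq[i], seq[j]):
                continue
            best = model.loop_penalty("hairpin", j - i - 1)
            best_choice: tuple[int, int] | None = None
            for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
                if k - i - 1 > MAX_INTERNAL:
                    break
                for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                    if (k, l) not in V:
                        continue
                    if not model.admissible(i, j, k, l):
                        continue
                    e = model.transition(seq, i, j, k, l) + V[(k, l)]
                    if e < best:
                        best = e
                        best_choice = (k, l)
            V[(i, j)] = best
            choice[(i, j)] = best_choice
    return V, choice


def fold_mfe(sequence: str, allow_gt_wobble: bool = False) -> FoldResult:
    """Minimum-free-energy structure of a 13-31 nt DNA window.

    Returns the empty structure with delta_g = 0 when no structure
    reaches a negative free energy.  Ties are broken deterministically
    by a fixed traceback scan order.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    model = EnergyModel(allow_gt_wobble=allow_gt_wobble)
    V, choice = _fill_v(seq, model)

    # exterior: W[t] = best energy of prefix seq[:t], multiple hairpins allowed
    W = [0.0] * (n + 1)
    back: list[int | None] = [None] * (n + 1)
    for t in range(1, n + 1):
        best = W[t - 1]
        best_i: int | None = None
        for i in range(0, t - 1):
            if (i, t - 1) in V:
                e = W[i] + V[(i, t - 1)]
                if e < best:
                    best = e
                    best_i = i
        W[t] = best
        back[t] = best_i

    mfe = W[n]
    pairing = [0] * n
    if mfe < 0:
        t = n
        while t > 0:
            i = back[t]
            if i is None:
                t -= 1
                continue
            a, b = i, t - 1
            while True:
                pairing[a] = b + 1
                pairing[b] = a + 1
                nxt = choice[(a, b)]
                if nxt is None:
                    break
                a, b = nxt
            t = i
    else:
        mfe = 0.0

    centre = n // 2
    in_loop = False
    closing: tuple[int, int] | None = None
    if pairing[centre] == 0:
        # innermost pairs: those with no pair strictly inside
        pairs = [
            (p, q - 1) for p, q in enumerate(pairing) if q and p < q - 1
        ]
        for a, b in pairs:
            if a < centre < b and not any(a < x and y < b for x, y in pairs if (x, y) != (a, b)):
                in_loop = True
                closing = (a, b)
                break
    return FoldResult(
        sequence=seq,
        pairing=tuple(pairing),
        delta_g=float(mfe),
        centre_in_loop=in_loop,
        loop_closing_pair=closing,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle-grade, exponential; small n only)
# ---------------------------------------------------------------------------

def enumerate_structures(sequence: str, allow_gt_wobble: bool = False):
    """Yield every admissible structure (pair set, energy); brute force.

    Admissibility matches :func:`fold_mfe`'s structure class: disjoint
    single-branch hairpin chains with the same loop-size caps.  Intended
    as an independent search for small windows; energies are computed
    per structure by :func:`energy_of_structure`.
    """
    seq = sequence.upper()
    n = len(seq)
    model = EnergyModel(allow_gt_wobble=allow_gt_wobble)

    def chains(i, j):
        # all chains whose outermost pair is exactly (i, j)
        out = []
        if j - i - 1 >= MIN_HAIRPIN_LOOP:
            out.append(((i, j),))
        for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
            for l in range(k + MIN_HAIRPIN_LOOP + 1, j):
                if not model.pairable(seq[k], seq[l]):
                    continue
                if not model.admissible(i, j, k, l):
                    continue
                for sub in chains(k, l):
                    out.append(((i, j),) + sub)
        return out

    def region(i, j):
        if i > j:
            yield ()
            return
        yield from region(i + 1, j)
        for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not model.pairable(seq[i], seq[l]):
                continue
            for chain in chains(i, l):
                for rest in region(l + 1, j):
                    yield chain + rest

    for structure in region(0, n - 1):
        if not structure:
            yield frozenset(), 0.0
        else:
            yield frozenset(structure), energy_of_structure(seq, structure, model)


def enumeration_mfe(sequence: str, allow_gt_wobble: bool = False) -> float:
    """Brute-force MFE over the admissible structure class (min 0)."""
    best = 0.0
    for _, e in enumerate_structures(sequence, allow_gt_wobble):
        if e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# window escalation
# ---------------------------------------------------------------------------

@dataclass
class EscalationReport:
    """Per-length folds of centred windows and stem-completion summary."""

    folds: dict[int, FoldResult] = field(default_factory=dict)
    centre_stems: dict[int, frozenset] = field(default_factory=dict)
    completion_length: int | None = None
    secondary_first_length: int | None = None


def window_escalation_scan(
    context: str,
    lengths: tuple[int, ...] = (13, 17, 21, 25, 29),
    allow_gt_wobble: bool = False,
) -> EscalationReport:
    """Fold centred windows of increasing length around one site.

    The centre stem at each length is the set of pairs enclosing (or
    pairing) the centre, in centre-relative coordinates.  The completion
    length is the smallest scanned length from which that stem stays
    identical at every longer scanned length; the report also records
    the first length at which secondary stems (pairs not involving the
    centre's stem) appear.
    """
    context = context.upper()
    centre = len(context) // 2
    report = EscalationReport()
    usable = [L for L in lengths if L % 2 == 1 and centre - L // 2 >= 0 and centre + L // 2 < len(context)]
    for L in usable:
        flank = L // 2
        window = context[centre - flank : centre + flank + 1]
        fr = fold_mfe(window, allow_gt_wobble=allow_gt_wobble)
        report.folds[L] = fr
        stem = frozenset(
            (a - flank, b - flank) for a, b in fr.pairs if a <= flank <= b
        )
        report.centre_stems[L] = stem
        has_secondary = any(not (a <= flank <= b) for a, b in fr.pairs)
        if has_secondary and report.secondary_first_length is None:
            report.secondary_first_length = L
    for idx, L in enumerate(usable):
        stem = report.centre_stems[L]
        if not stem:
            continue
        if all(report.centre_stems[M] == stem for M in usable[idx + 1 :]):
            report.completion_length = L
            break
    return report


# ---------------------------------------------------------------------------
# normalised loop stability
# ---------------------------------------------------------------------------

def normalised_loop_stability(features) -> list[LoopFeature]:
    """Min-max rescale the in-loop free energies of a panel.

    ``features`` is an iterable of ``(key, delta_g, in_loop)``.  In-loop
    entries with negative free energy are rescaled so the most stable
    loop maps to 0 and the least stable qualifying loop to 1; every
    other entry (not in a loop, or delta_g >= 0) scores 1.
    """
    feats = [(k, float(dg), bool(il)) for k, dg, il in features]
    qualifying = [dg for _, dg, il in feats if il and dg < 0]
    out = []
    if qualifying:
        lo, hi = min(qualifying), max(qualifying)
        degenerate = hi == lo
        if degenerate and len(qualifying) > 1:
            logger.warning("degenerate loop-stability range; qualifying scores set to 0")
    for key, dg, il in feats:
        if il and dg < 0:
            score = 0.0 if hi == lo else (dg - lo) / (hi - lo)
        else:
            score = 1.0
        out.append(LoopFeature(key=key, delta_g=dg, in_loop=il, normalised_score=float(score)))
    return out


def matched_null_quantiles(
    cohort,
    gene_ranks: pd.Series,
    passengers,
    n_draws: int = 1000,
    seed=None,
    tol: float = 0.01,
    exclude_genes=(),
):
    """Expression-matched null distribution of loop free energies.

    Builds the pool of non-recurrent APOBEC-motif mutations in genes
    whose expression percentile rank lies within ``tol`` of any
    known-passenger gene's rank, samples ``n_draws`` of them without
    replacement, folds their 25-nt windows and records the free energy
    (0 when the site is not in a loop or the energy is non-negative).
    Returns ``(quantiles, null)`` where ``quantiles[i]`` is the i-th
    passenger's position in the null empirical distribution.

    ``passengers`` is a list of ``(gene, delta_g, in_loop)``.
    """
    from .hotspots import annotate_apobec_motif, tally_recurrence

    rng = np.random.default_rng(seed)
    passenger_ranks = np.array([gene_ranks[g] for g, _, _ in passengers])
    matched = {
        g
        for g, r in gene_ranks.items()
        if np.min(np.abs(passenger_ranks - r)) <= tol
    }
    matched -= set(exclude_genes)

    table = tally_recurrence(cohort)
    seen = set()
    pool = []
    for rec in cohort.records:
        if rec.gene not in matched or rec.key in seen:
            continue
        if table.entries[rec.key].count != 1:
            continue
        ctx5 = rec.central_context(2)
        ctx25 = rec.central_context(12)
        if ctx5 is None or ctx25 is None:
            continue
        if annotate_apobec_motif(ctx5, rec.ref, rec.alt)[0] != "APOBEC_TCN":
            continue
        seen.add(rec.key)
        pool.append(ctx25)

    if len(pool) < n_draws:
        logger.warning(
            "matched pool (%d) smaller than n_draws (%d); using whole pool",
            len(pool), n_draws,
        )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n_draws, replace=False)
        chosen = [pool[i] for i in idx]

    null = []
    for ctx in chosen:
        fr = fold_mfe(ctx)
        null.append(fr.delta_g if (fr.centre_in_loop and fr.delta_g < 0) else 0.0)
    null = np.asarray(null)

    quantiles = []
    for _, dg, il in passengers:
        val = dg if (il and dg < 0) else 0.0
        quantiles.append(float(np.mean(null <= val)))
    return np.asarray(quantiles), null
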