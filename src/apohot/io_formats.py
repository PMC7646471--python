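"""Readers and writers for the on-disk formats the pipeline touches.

Somatic SNVs arrive as MAF-like TSV tables (one row per mutation per
sample), replication-fork-directionality (RFD) tracks as bedGraph,
expression and signature references as TSV matrices.  SNV positions are
1-based; bedGraph intervals are 0-based half-open.  Sequence context is
stored on the plus strand; pyrimidine-strand conversion happens in the
analysis modules, never here.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("apohot")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: canonical 96-channel order: 6 pyrimidine substitutions x 16 flanking
#: contexts, both in lexicographic order (COSMIC convention).
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_DATA_DIR = Path(__file__).parent / "data"


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide variant in one sample.

    ``pos`` is 1-based.  ``context25`` is the plus-strand reference
    sequence of the 25-nt window centred on ``pos`` (12 nt each side);
    its middle base must equal ``ref``.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str | None = None
    context25: str | None = None
    clonality: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.clonality is not None and self.clonality not in (
            "clonal", "subclonal", "unknown"
        ):
            raise ValueError(f"bad clonality label {self.clonality!r}")
        if self.context25 is not None:
            ctx = self.context25
            if len(ctx) != 25:
                raise ValueError(f"context25 must be 25 nt, got {len(ctx)}")
            if ctx[12] != self.ref:
                raise ValueError(
                    f"context25 middle base {ctx[12]} != ref {self.ref} "
                    f"at {self.chrom}:{self.pos}"
                )

    def central_context(self, flank: int) -> str | None:
        """Plus-strand window of ``2*flank+1`` nt centred on the site.

        Returns None when the stored context is absent, too short, or
        contains an ambiguous base within the window.
        """
        if self.context25 is None:
            return None
        if flank > 12:
            return None
        window = self.context25[12 - flank : 13 + flank]
        if any(b not in "ACGT" for b in window):
            return None
        return window

    @property
    def is_ambiguous(self) -> bool:
        """True when the central +/-2 nt window carries an N."""
        if self.context25 is None:
            return False
        return any(b == "N" for b in self.context25[10:15])


@dataclass
class CohortTable:
    """A de-duplicated tumour cohort: at most one sample per patient."""

    records: list[SnvRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len({r.sample_id for r in self.records})

    @property
    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RfdTrack:
    """Replication fork directionality along one genome, one cell line.

    Intervals are 0-based half-open ``(chrom, start, end, rfd)`` with
    ``rfd`` in [-1, 1]; positive values mark regions where the Watson
    strand is replicated mostly as the lagging-strand template.
    """

    cell_line: str
    intervals: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1]))
        self._index: dict[str, tuple[list[int], list[int], list[float]]] = {}
        prev: dict[str, int] = {}
        for chrom, start, end, value in self.intervals:
            if not np.isfinite(value) or not (-1.0 <= value <= 1.0):
                raise FormatError(f"RFD value {value} outside [-1, 1]")
            if end <= start:
                raise FormatError(f"empty interval {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise FormatError(
                    f"overlapping intervals on {chrom} near {start}"
                )
            prev[chrom] = end
            starts, ends, values = self._index.setdefault(chrom, ([], [], []))
            starts.append(start)
            ends.append(end)
            values.append(value)

    def value_at(self, chrom: str, pos: int) -> float | None:
        """RFD at a 1-based position, or None when uncovered."""
        if chrom not in self._index:
            return None
        starts, ends, values = self._index[chrom]
        i = bisect_right(starts, pos - 1) - 1
        if i >= 0 and pos - 1 < ends[i]:
            return values[i]
        return None


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    units: str = "normalised"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene symbols: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SignatureMatrix:
    """Reference mutational signatures: profiles over the 96 channels.

    Each row is a probability distribution over :data:`CHANNELS_96`.
    """

    profiles: pd.DataFrame  # index = signature ids, columns = CHANNELS_96

    def __post_init__(self) -> None:
        if tuple(self.profiles.columns) != CHANNELS_96:
            missing = set(CHANNELS_96) - set(self.profiles.columns)
            if missing:
                raise FormatError(f"missing channels: {sorted(missing)[:4]} ...")
            self.profiles = self.profiles.loc[:, list(CHANNELS_96)]
        arr = self.profiles.to_numpy(dtype=float)
        if (arr < 0).any():
            raise FormatError("signature profiles must be non-negative")
        sums = arr.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            if np.abs(sums - 1.0).max() > 1e-6:
                logger.warning(
                    "signature rows deviate from unit sum (max dev %.2e); "
                    "renormalising", np.abs(sums - 1.0).max(),
                )
            self.profiles = self.profiles.div(sums, axis=0)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.profiles.index)


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------

_REQUIRED_SNV_COLUMNS = ("patient", "sample", "chrom", "pos", "ref", "alt", "gene")
_OPTIONAL_SNV_COLUMNS = ("protein_change", "context25", "clonality")


def dedup_samples(records: list[SnvRecord]) -> list[SnvRecord]:
    """Keep one sample per patient: the lexicographically smallest sample id.

    Idempotent by construction.
    """
    chosen: dict[str, str] = {}
    for rec in records:
        cur = chosen.get(rec.patient_id)
        if cur is None or rec.sample_id < cur:
            chosen[rec.patient_id] = rec.sample_id
    return [r for r in records if chosen[r.patient_id] == r.sample_id]


def _context_from_fasta(fasta, chrom: str, pos: int) -> str | None:
    try:
        seq = fasta[chrom][pos - 13 : pos + 12]
    except KeyError:
        return None
    seq = str(seq).upper()
    if len(seq) != 25:
        return None
    return seq


def read_snv_table(path, fasta=None) -> CohortTable:
    """Read a MAF-like SNV TSV into a validated, de-duplicated cohort.

    Required columns: patient, sample, chrom, pos, ref, alt, gene.
    When ``fasta`` (a path or a pyfaidx.Fasta) is given, missing contexts
    are filled from the reference (+/-12 nt) and records whose ref base
    disagrees with the reference are dropped (counted in metadata).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SNV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if fasta is not None and not hasattr(fasta, "keys"):
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta), sequence_always_upper=True)

    records: list[SnvRecord] = []
    n_rejected = 0
    n_ref_mismatch = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        ctx = d.get("context25") or None
        clon = d.get("clonality") or None
        rec = SnvRecord(
            patient_id=d["patient"],
            sample_id=d["sample"],
            chrom=d["chrom"],
            pos=int(d["pos"]),
            ref=d["ref"].upper(),
            alt=d["alt"].upper(),
            gene=d["gene"],
            protein_change=d.get("protein_change") or None,
            context25=ctx.upper() if ctx else None,
            clonality=clon,
        )
        if rec.context25 is None and fasta is not None:
            filled = _context_from_fasta(fasta, rec.chrom, rec.pos)
            if filled is not None:
                if filled[12] != rec.ref:
                    n_ref_mismatch += 1
                    continue
                rec = replace(rec, context25=filled)
        try:
            rec.validate()
        except ValueError as exc:
            n_rejected += 1
            logger.warning("rejected record: %s", exc)
            continue
        records.append(rec)

    records = dedup_samples(records)
    n_ambiguous = sum(r.is_ambiguous for r in records)
    if n_rejected:
        logger.warning("rejected %d invalid records", n_rejected)
    return CohortTable(
        records=records,
        metadata={
            "n_rejected": n_rejected,
            "n_ref_mismatch": n_ref_mismatch,
            "n_ambiguous": n_ambiguous,
            "source": str(path),
        },
    )


def write_snv_table(cohort: CohortTable, path) -> None:
    rows = []
    for r in cohort.records:
        rows.append(
            {
                "patient": r.patient_id,
                "sample": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "protein_change": r.protein_change or "",
                "context25": r.context25 or "",
                "clonality": r.clonality or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RFD bedGraph
# ---------------------------------------------------------------------------

def read_rfd_bedgraph(path, cell_line: str) -> RfdTrack:
    """Read a 4-column bedGraph of RFD values into a sorted track."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"bad bedGraph line: {line!r}")
            chrom, start, end, value = fields[:4]
            intervals.append((chrom, int(start), int(end), float(value)))
    return RfdTrack(cell_line=cell_line, intervals=intervals)


def write_rfd_bedgraph(track: RfdTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# expression & signature matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path, units: str = "normalised") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), units=units)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_signature_reference(path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SignatureMatrix(profiles=df.astype(float))


def write_signature_reference(sig: SignatureMatrix, path) -> None:
    sig.profiles.to_csv(path, sep="\t", index_label="signature")


def load_packaged_signature_reference() -> SignatureMatrix:
    """The packaged synthetic 30-signature reference.

    A synthetic stand-in for the COSMIC v2 catalogue: 30 profiles over
    the 96 channels with APOBEC-like profiles in slots 2 and 13 (TCN
    C>T / C>G), a deamination/ageing-like slot 1 and a flat slot 5.
    """
    return read_signature_reference(_DATA_DIR / "signatures_synthetic30.tsv")


def load_packaged_hotspot_panel() -> pd.DataFrame:
    """Published panel of 44 APOBEC-associated hotspot mutations.

    Gene symbol, protein change and carrier count from a 602-exome
    bladder-cancer cohort; packaged as a curated text fixture.
    """
    return pd.read_csv(_DATA_DIR / "bca_apobec_hotspot_panel.tsv", sep="\t")
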