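"""Training-set construction from annotated protein sequences.

Positive examples are fixed-length windows (default 27 residues: 13 up-
and 13 downstream) centered on experimentally annotated phospho-S/T/Y
sites, padded with the pseudo-residue ``O`` where the window overruns the
protein's ends.  Negative candidates are the remaining residues of the
same type lying more than an exclusion distance (default 50 residues)
from every annotated site of their protein.  Because negatives vastly
outnumber positives, R balanced replicates (default 10) are drawn, each
pairing all positives with an equal-size uniform sample of negatives;
downstream models are trained per replicate and ensembled.

Coordinates are 1-based and inclusive throughout the public interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity/rare letters accepted on read; windows containing them are dropped.
AMBIGUOUS_AA = set("XBZU")
PAD = "O"
ACCEPTOR_RESIDUES = ("S", "T", "Y")

DEFAULT_HALF_WINDOW = 13
DEFAULT_EXCLUSION = 50
DEFAULT_REPLICATES = 10


class ParseError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when annotations contradict the sequences they reference."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its annotated phosphosite positions (1-based)."""

    id: str
    sequence: str
    sites: frozenset = frozenset()

    def __post_init__(self):
        for p in self.sites:
            if not 1 <= p <= len(self.sequence):
                raise ValidationError(
                    f"protein {self.id}: site position {p} outside sequence "
                    f"of length {len(self.sequence)}"
                )
            if self.sequence[p - 1] not in ACCEPTOR_RESIDUES:
                raise ValidationError(
                    f"protein {self.id}: annotated residue at position {p} is "
                    f"{self.sequence[p - 1]!r}, expected one of S/T/Y"
                )

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteFragment:
    """A window of 2n+1 residues centered on a candidate S/T/Y site."""

    protein_id: str
    position: int
    residue_type: str
    window: str
    label: str | None = None  # "positive", "negative", or None if unset

    def __post_init__(self):
        L = len(self.window)
        if L % 2 == 0:
            raise ValidationError(f"window length must be odd, got {L}")
        center = L // 2
        if self.window[center] != self.residue_type:
            raise ValidationError(
                f"center of window {self.window!r} is {self.window[center]!r}, "
                f"expected {self.residue_type!r}"
            )
        if PAD in self.window.strip(PAD):
            raise ValidationError(
                f"padding letter {PAD} occurs away from the window ends in "
                f"{self.window!r}"
            )
        if self.label not in (None, "positive", "negative"):
            raise ValidationError(f"invalid label {self.label!r}")


@dataclass(frozen=True)
class BalancedSet:
    """One balanced training replicate: all positives + an equal negative draw."""

    replicate_index: int
    positives: tuple
    negatives: tuple
    seed: int
    residue_type: str

    def __post_init__(self):
        if len(self.positives) != len(self.negatives):
            raise ValidationError(
                f"replicate {self.replicate_index}: {len(self.positives)} "
                f"positives vs {len(self.negatives)} negatives"
            )

    @property
    def fragments(self) -> list:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences; ids are the first header token, bodies uppercased.

    The 20 standard amino acids plus the ambiguity letters X/B/Z/U are
    accepted; anything else (digits, gaps, stray symbols) is a parse
    error naming the offending record.
    """
    records = []
    allowed = STANDARD_AA | AMBIGUOUS_AA
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        bad = set(seq) - allowed
        if bad:
            raise ParseError(
                f"record {rec.id!r}: invalid characters {sorted(bad)} in sequence"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, len(prot.sequence), width):
                fh.write(prot.sequence[i : i + width] + "\n")


ANNOTATION_COLUMNS = ["protein_id", "position", "residue"]


def read_site_annotations(path, proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach annotated sites from a TSV to their proteins.

    The table has a header row ``protein_id  position  residue`` (tab-
    separated, 1-based positions, '#' comment lines skipped).  Each row
    is validated against the sequence: the named residue must be present
    at the stated position.  Duplicate rows collapse to one site with a
    logged warning.
    """
    df = pd.read_csv(str(path), sep="\t", comment="#", dtype={"protein_id": str})
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ParseError(
            f"annotation header must be {ANNOTATION_COLUMNS}, got {list(df.columns)}"
        )
    by_id = {p.id: p for p in proteins}
    sites: dict[str, set[int]] = {p.id: set() for p in proteins}
    for row in df.itertuples(index=False):
        pid, pos, res = row.protein_id, int(row.position), str(row.residue)
        if pid not in by_id:
            raise ValidationError(f"annotation references unknown protein {pid!r}")
        prot = by_id[pid]
        if not 1 <= pos <= len(prot.sequence):
            raise ValidationError(
                f"protein {pid}: position {pos} out of range 1..{len(prot.sequence)}"
            )
        found = prot.residue(pos)
        if found != res:
            raise ValidationError(
                f"protein {pid}, position {pos}: annotation says {res!r} "
                f"but sequence has {found!r}"
            )
        if pos in sites[pid]:
            logger.warning(
                "duplicate annotation for protein %s position %d; keeping one",
                pid,
                pos,
            )
        sites[pid].add(pos)
    return [replace(p, sites=frozenset(sites[p.id])) for p in proteins]


def write_site_annotations(proteins: list[ProteinRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for prot in proteins:
            for pos in sorted(prot.sites):
                fh.write(f"{prot.id}\t{pos}\t{prot.residue(pos)}\n")


def extract_fragment(
    protein: ProteinRecord,
    position: int,
    n: int = DEFAULT_HALF_WINDOW,
    label: str | None = None,
) -> SiteFragment:
    """Cut the 2n+1 window centered at ``position``, padding overruns with O."""
    if not 1 <= position <= len(protein.sequence):
        raise ValidationError(
            f"protein {protein.id}: position {position} out of range"
        )
    residue = protein.residue(position)
    if residue not in ACCEPTOR_RESIDUES:
        raise ValidationError(
            f"protein {protein.id}, position {position}: central residue "
            f"{residue!r} is not S/T/Y"
        )
    L = len(protein.sequence)
    left = max(position - n, 1)
    right = min(position + n, L)
    window = (
        PAD * (left - (position - n))
        + protein.sequence[left - 1 : right]
        + PAD * ((position + n) - right)
    )
    return SiteFragment(
        protein_id=protein.id,
        position=position,
        residue_type=residue,
        window=window,
        label=label,
    )


def window_is_standard(fragment: SiteFragment) -> bool:
    """True when the window uses only the 20 amino acids plus padding O."""
    return all(c in STANDARD_AA or c == PAD for c in fragment.window)


def select_negative_positions(
    protein: ProteinRecord, residue_type: str, d: int = DEFAULT_EXCLUSION
) -> list[int]:
    """Positions of ``residue_type`` eligible as negatives under the exclusion rule.

    A position qualifies when it is not itself annotated and lies strictly
    more than ``d`` residues from every annotated site of the protein
    (sites of any acceptor type count).
    """
    if d < 0:
        raise ValueError(f"exclusion distance must be non-negative, got {d}")
    out = []
    sites = sorted(protein.sites)
    for p0, c in enumerate(protein.sequence):
        p = p0 + 1
        if c != residue_type or p in protein.sites:
            continue
        if all(abs(p - s) > d for s in sites):
            out.append(p)
    return out


def build_balanced_sets(
    proteins: list[ProteinRecord],
    residue_type: str,
    n: int = DEFAULT_HALF_WINDOW,
    d: int = DEFAULT_EXCLUSION,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[BalancedSet]:
    """Build R balanced replicates for one acceptor residue type.

    Positive fragments are fixed; negatives are pooled over all proteins
    and each replicate draws uniformly without replacement (independently
    across replicates).  Windows containing ambiguity letters are dropped
    with a warning.  Per-replicate seeds are derived from ``seed`` and
    recorded on each BalancedSet, so any replicate can be rebuilt exactly.
    """
    if residue_type not in ACCEPTOR_RESIDUES:
        raise ValueError(f"residue_type must be one of S/T/Y, got {residue_type!r}")
    positives = []
    pool = []
    for prot in proteins:
        for pos in sorted(prot.sites):
            if prot.residue(pos) != residue_type:
                continue
            frag = extract_fragment(prot, pos, n, label="positive")
            if window_is_standard(frag):
                positives.append(frag)
            else:
                logger.warning(
                    "dropping positive %s:%d (ambiguous residue in window)",
                    prot.id,
                    pos,
                )
        for pos in select_negative_positions(prot, residue_type, d):
            frag = extract_fragment(prot, pos, n, label="negative")
            if window_is_standard(frag):
                pool.append(frag)
            else:
                logger.warning(
                    "dropping negative %s:%d (ambiguous residue in window)",
                    prot.id,
                    pos,
                )
    if len(pool) < len(positives):
        raise ValidationError(
            f"negative pool ({len(pool)}) smaller than positive count "
            f"({len(positives)}); cannot balance"
        )
    rep_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=replicates
    )
    sets = []
    for r, rep_seed in enumerate(rep_seeds, start=1):
        rng = np.random.default_rng(int(rep_seed))
        idx = rng.choice(len(pool), size=len(positives), replace=False)
        negatives = tuple(pool[i] for i in sorted(idx))
        sets.append(
            BalancedSet(
                replicate_index=r,
                positives=tuple(positives),
                negatives=negatives,
                seed=int(rep_seed),
                residue_type=residue_type,
            )
        )
    return sets


def rebuild_replicate(
    proteins: list[ProteinRecord],
    residue_type: str,
    rep_seed: int,
    replicate_index: int = 1,
    n: int = DEFAULT_HALF_WINDOW,
    d: int = DEFAULT_EXCLUSION,
) -> BalancedSet:
    """Reconstruct one BalancedSet from its recorded per-replicate seed."""
    positives = []
    pool = []
    for prot in proteins:
        for pos in sorted(prot.sites):
            if prot.residue(pos) != residue_type:
                continue
            frag = extract_fragment(prot, pos, n, label="positive")
            if window_is_standard(frag):
                positives.append(frag)
        for pos in select_negative_positions(prot, residue_type, d):
            frag = extract_fragment(prot, pos, n, label="negative")
            if window_is_standard(frag):
                pool.append(frag)
    rng = np.random.default_rng(int(rep_seed))
    idx = rng.choice(len(pool), size=len(positives), replace=False)
    return BalancedSet(
        replicate_index=replicate_index,
        positives=tuple(positives),
        negatives=tuple(pool[i] for i in sorted(idx)),
        seed=int(rep_seed),
        residue_type=residue_type,
    )


FRAGMENT_COLUMNS = ["protein_id", "position", "residue", "label", "window"]


def write_fragments(fragments: list[SiteFragment], path) -> None:
    """Write fragments as TSV: protein_id, position, residue, label, window."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FRAGMENT_COLUMNS) + "\n")
        for f in fragments:
            fh.write(
                f"{f.protein_id}\t{f.position}\t{f.residue_type}\t"
                f"{f.label or ''}\t{f.window}\n"
            )


def read_fragments(path) -> list[SiteFragment]:
    """Read a fragment TSV written by :func:`write_fragments`."""
    df = pd.read_csv(
        str(path), sep="\t", comment="#", dtype={"protein_id": str}, keep_default_na=False
    )
    if list(df.columns) != FRAGMENT_COLUMNS:
        raise ParseError(
            f"fragment header must be {FRAGMENT_COLUMNS}, got {list(df.columns)}"
        )
    return [
        SiteFragment(
            protein_id=row.protein_id,
            position=int(row.position),
            residue_type=str(row.residue),
            window=str(row.window),
            label=str(row.label) or None,
        )
        for row in df.itertuples(index=False)
    ]
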