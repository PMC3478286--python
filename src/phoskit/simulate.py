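"""Synthetic annotated proteomes with planted phosphosite motifs.

Real phosphosite training data consists of protein sequences in which a
subset of S/T/Y residues is experimentally annotated and the sequence
neighborhood of true sites is enriched for short kinase-recognition
motifs (proline-directed SP, basophilic R-x-x-S, and the like).  The
generator emulates exactly that structure: background sequences drawn
from a residue composition, Poisson-distributed annotated sites chosen
among residues of the acceptor type, and each configured motif planted
into a site's neighborhood with its planting probability.  Everything is
reproducible from a single seed, and the emitted FASTA/annotation files
are byte-identical across runs.

With all planting probabilities at zero the positive and negative
windows are statistically identical — the null generator for calibration
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ProteinRecord, write_fasta, write_site_annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Default motifs per acceptor type, with planting probabilities chosen to
#: mimic the coverage of the dominant kinase motif classes (proline-directed
#: SP/TP on roughly half of S/T sites, basophilic and acidophilic context on
#: a further fraction).
DEFAULT_MOTIFS = {
    "S": (("SP", 0.5), ("S×S", 0.35), ("R××S", 0.35)),
    "T": (("TP", 0.5), ("T×P", 0.35), ("T×××T", 0.25)),
    "Y": (("D×Y", 0.5), ("Y××P", 0.35)),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic proteome."""

    n_proteins: int = 200
    length_range: tuple = (100, 500)
    background: tuple | None = None  # composition over AA20; None = uniform
    sites_per_protein: float = 2.0  # Poisson mean
    motifs: tuple | None = None  # ((label, planting probability), ...)
    residue_type: str = "S"
    seed: int = 0
    half_window: int = 13
    id_prefix: str = "syn"

    def resolved_motifs(self) -> tuple:
        motifs = self.motifs
        if motifs is None:
            motifs = DEFAULT_MOTIFS[self.residue_type]
        for label, p in motifs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"planting probability {p} for {label!r} not in [0,1]")
            for off, letter in parse_motif(label):
                if letter not in AA20:
                    raise ValueError(
                        f"motif {label!r} uses non-standard letter {letter!r}"
                    )
        return tuple(motifs)


def parse_motif(label: str) -> list[tuple[int, str]]:
    """Parse a pair label like ``R××S`` into (offset, letter) pairs.

    Gap characters (×, x, X or .) are wildcards; offsets are relative to
    the motif's first letter.
    """
    out = []
    for i, c in enumerate(label):
        if c in ("×", "x", "X", "."):
            continue
        out.append((i, c))
    if not out:
        raise ValueError(f"motif {label!r} contains no residue letters")
    return out


def motif_anchor(label: str, residue_type: str) -> int:
    """Offset of the motif's first letter relative to the window center.

    If the acceptor letter occurs in the motif, its first occurrence is
    aligned to the central residue (so ``R××S`` puts R three positions
    upstream of the site).  Motifs without the acceptor letter are
    planted immediately downstream of it.
    """
    letters = parse_motif(label)
    for off, c in letters:
        if c == residue_type:
            return -off
    return 1


def simulate(spec: SimulationSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate annotated proteins and the ground-truth planting table.

    Returns the protein records (sites filled) and a DataFrame with one
    row per planted motif instance: protein_id, position, motif.
    Planting never overwrites an annotated site's acceptor residue.
    """
    motifs = spec.resolved_motifs()
    span = 2 * spec.half_window + 1
    for label, _ in motifs:
        if len(label) > span:
            raise ValueError(
                f"motif {label!r} longer than the {span}-residue window"
            )
    lo, hi = spec.length_range
    if spec.background is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.asarray(spec.background, dtype=float)
        probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AA20))
    proteins = []
    truth_rows = []
    for i in range(spec.n_proteins):
        pid = f"{spec.id_prefix}{i + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(letters, size=L, p=probs))
        candidates = [p for p in range(1, L + 1) if seq[p - 1] == spec.residue_type]
        n_sites = min(int(rng.poisson(spec.sites_per_protein)), len(candidates))
        site_positions = sorted(
            int(p) for p in rng.choice(candidates, size=n_sites, replace=False)
        )
        site_set = set(site_positions)
        for pos in site_positions:
            for label, p_plant in motifs:
                if rng.random() >= p_plant:
                    continue
                start = pos + motif_anchor(label, spec.residue_type)
                planted = False
                for off, letter in parse_motif(label):
                    target = start + off
                    if not 1 <= target <= L:
                        continue
                    # never clobber an annotated acceptor (incl. the center)
                    if target in site_set and letter != spec.residue_type:
                        continue
                    seq[target - 1] = letter
                    planted = True
                if planted:
                    truth_rows.append({"protein_id": pid, "position": pos, "motif": label})
        proteins.append(
            ProteinRecord(id=pid, sequence="".join(seq), sites=frozenset(site_set))
        )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "position", "motif"])
    return proteins, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def simulate_to_files(spec: SimulationSpec, fasta_path, sites_path, truth_path=None):
    """Run :func:`simulate` and emit FASTA + annotation TSV (+ truth TSV)."""
    proteins, truth = simulate(spec)
    write_fasta(proteins, fasta_path)
    write_site_annotations(proteins, sites_path)
    if truth_path is not None:
        write_truth(truth, truth_path)
    return proteins, truth
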