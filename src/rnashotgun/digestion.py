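"""Modification-annotated tRNA sequences and in-silico RNase T1 digestion.

RNase T1 cleaves 3' of guanosine, leaving 5'-OH and a 2',3'-cyclic phosphate
that opens to a linear 3'-phosphate; 2'-O-methylated G (Gm) blocks cleavage.
Fragments are produced with configurable missed cleavages and 3'-end
chemistry, in deterministic (start, end) order; the parent molecule's own 3'
terminus keeps its hydroxyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .chem import ElementalComposition, HPO3, WATER, ModRegistry, RegistryError

__all__ = [
    "ModifiedRNASequence",
    "Fragment",
    "parse_annotated_sequence",
    "read_annotated_fasta",
    "digest_rnase_t1",
    "fragment_composition",
    "fragment_mass",
    "fragments_to_tsv",
]

FIVE_PRIME_CHEMS = ("OH", "phosphate")
THREE_PRIME_CHEMS = ("OH", "linear_phosphate", "cyclic_phosphate")


class AnnotationError(ValueError):
    """Modification table row incompatible with the sequence or registry."""


@dataclass(frozen=True)
class ModifiedRNASequence:
    """A residue-code sequence with an optional wobble (position 34) marker."""

    id: str
    residues: tuple[str, ...]
    anticodon_index: Optional[int] = None  # 1-based

    def __post_init__(self) -> None:
        if self.anticodon_index is not None and not (
            1 <= self.anticodon_index <= len(self.residues)
        ):
            raise AnnotationError(
                f"{self.id}: anticodon index {self.anticodon_index} outside 1..{len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def with_wobble_state(self, code: str, registry: ModRegistry) -> "ModifiedRNASequence":
        """Return a copy with the wobble residue replaced by ``code``."""
        if self.anticodon_index is None:
            raise AnnotationError(f"{self.id}: no anticodon index annotated")
        i = self.anticodon_index - 1
        current = registry.get(self.residues[i])
        new = registry.get(code)
        if new.parent != current.parent:
            raise AnnotationError(
                f"{self.id}: state {code!r} (parent {new.parent}) incompatible with "
                f"wobble residue {self.residues[i]!r} (parent {current.parent})"
            )
        residues = self.residues[:i] + (code,) + self.residues[i + 1 :]
        return ModifiedRNASequence(self.id, residues, self.anticodon_index)


@dataclass(frozen=True)
class Fragment:
    """A digest product: a parent slice with end chemistry."""

    parent_id: str
    start: int  # 1-based inclusive
    end: int
    residues: tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "linear_phosphate"
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.five_prime not in FIVE_PRIME_CHEMS:
            raise ValueError(f"unknown 5' chemistry {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_CHEMS:
            raise ValueError(f"unknown 3' chemistry {self.three_prime!r}")
        if len(self.residues) != self.end - self.start + 1:
            raise ValueError("residue list does not match coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def locus(self) -> str:
        return f"{self.start}-{self.end}"


def parse_annotated_sequence(
    seq_id: str,
    sequence: str,
    mod_rows: Iterable[tuple[int, str]],
    registry: ModRegistry,
    anticodon_index: Optional[int] = None,
) -> ModifiedRNASequence:
    """Apply (1-based position, modification code) rows to a plain base string.

    DNA-style T is normalized to U.  Each modification must resolve in the
    registry and its parent base must match the sequence letter at that
    position.
    """
    letters = sequence.upper().replace("T", "U")
    bad = set(letters) - set("ACGU")
    if bad:
        raise AnnotationError(f"{seq_id}: non-RNA letters {sorted(bad)}")
    residues = list(letters)
    for pos, code in mod_rows:
        if not (1 <= pos <= len(residues)):
            raise AnnotationError(
                f"{seq_id}: modification position {pos} outside 1..{len(residues)}"
            )
        definition = registry.get(code)  # raises RegistryError on unknown code
        if definition.parent != letters[pos - 1]:
            raise AnnotationError(
                f"{seq_id}: modification {code!r} at position {pos} has parent "
                f"{definition.parent}, sequence has {letters[pos - 1]}"
            )
        residues[pos - 1] = code
    return ModifiedRNASequence(seq_id, tuple(residues), anticodon_index)


def read_annotated_fasta(
    fasta_path: Union[str, Path],
    mod_table_path: Optional[Union[str, Path]],
    registry: ModRegistry,
    anticodon_indices: Optional[dict[str, int]] = None,
) -> list[ModifiedRNASequence]:
    """Load FASTA + modification TSV (seq_id, position, mod_code).

    The TSV may carry an optional ``anticodon`` column flagging the wobble
    position (value 1 on the row of the wobble residue); explicit
    ``anticodon_indices`` take precedence.
    """
    mods: dict[str, list[tuple[int, str]]] = {}
    wobble: dict[str, int] = dict(anticodon_indices or {})
    if mod_table_path is not None:
        table = pd.read_csv(mod_table_path, sep="\t", dtype={"seq_id": str, "mod_code": str})
        required = {"seq_id", "position", "mod_code"}
        if not required.issubset(table.columns):
            raise AnnotationError(
                f"modification table must have columns {sorted(required)}"
            )
        for row in table.itertuples(index=False):
            mods.setdefault(row.seq_id, []).append((int(row.position), row.mod_code))
            if "anticodon" in table.columns and getattr(row, "anticodon", 0) and row.seq_id not in wobble:
                wobble[row.seq_id] = int(row.position)
    out = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            parse_annotated_sequence(
                record.id,
                str(record.seq),
                mods.get(record.id, []),
                registry,
                anticodon_index=wobble.get(record.id),
            )
        )
    return out


def digest_rnase_t1(
    seq: ModifiedRNASequence,
    registry: ModRegistry,
    missed_cleavages: int = 0,
    three_prime_chem: str = "linear_phosphate",
) -> list[Fragment]:
    """In-silico RNase T1 digest with up to ``missed_cleavages`` skipped sites.

    Internal fragments carry 5'-OH and ``three_prime_chem``; the fragment
    containing the parent's 3' terminus keeps a 3'-OH.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    n = len(seq.residues)
    # segment boundaries: indices (0-based, exclusive) after each cleavable residue
    cut_after = [i + 1 for i, code in enumerate(seq.residues) if registry.is_cleavable(code)]
    bounds = [0] + cut_after
    if not cut_after or cut_after[-1] != n:
        bounds.append(n)
    # bounds delimit len(bounds)-1 contiguous segments
    fragments = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for k in range(missed_cleavages + 1):
            j = i + k
            if j >= nseg:
                break
            start, end = bounds[i], bounds[j + 1]
            # the molecule's own 3' terminus has no downstream phosphate to retain
            at_parent_end = end == n
            fragments.append(
                Fragment(
                    parent_id=seq.id,
                    start=start + 1,
                    end=end,
                    residues=seq.residues[start:end],
                    five_prime="OH",
                    three_prime="OH" if at_parent_end else three_prime_chem,
                    missed_cleavages=k,
                )
            )
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


def fragment_composition(frag: Fragment, registry: ModRegistry) -> ElementalComposition:
    """Neutral elemental composition of a fragment.

    Sum of nucleoside compositions, plus HPO3 per phosphate group (n−1
    internucleotide bridges plus any terminal phosphates), minus one water per
    condensation (each bridge, plus one more for a 2',3'-cyclic terminus).
    """
    comp = ElementalComposition()
    for code in frag.residues:
        comp = comp + registry.residue_composition(code)
    n = len(frag.residues)
    phosphates = n - 1
    waters = n - 1
    if frag.five_prime == "phosphate":
        phosphates += 1
    if frag.three_prime in ("linear_phosphate", "cyclic_phosphate"):
        phosphates += 1
    if frag.three_prime == "cyclic_phosphate":
        waters += 1
    return comp + phosphates * HPO3 - waters * WATER


def fragment_mass(frag: Fragment, registry: ModRegistry) -> float:
    """Neutral monoisotopic mass (Da) via the residue-sum bookkeeping."""
    n = len(frag.residues)
    phosphates = (n - 1) + int(frag.five_prime == "phosphate") + int(
        frag.three_prime in ("linear_phosphate", "cyclic_phosphate")
    )
    waters = (n - 1) + int(frag.three_prime == "cyclic_phosphate")
    residue_sum = sum(registry.residue_mass(code) for code in frag.residues)
    return residue_sum + phosphates * HPO3.mass() - waters * WATER.mass()


def fragments_to_tsv(
    fragments: Sequence[Fragment], registry: ModRegistry, path: Union[str, Path]
) -> pd.DataFrame:
    """Write the digest table (and return it as a DataFrame)."""
    rows = [
        {
            "parent_id": f.parent_id,
            "start": f.start,
            "end": f.end,
            "sequence": "-".join(f.residues),
            "five_prime": f.five_prime,
            "three_prime": f.three_prime,
            "missed_cleavages": f.missed_cleavages,
            "neutral_mass": round(fragment_mass(f, registry), 6),
        }
        for f in fragments
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
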