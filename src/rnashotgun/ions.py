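"""Negative-ion m/z arithmetic, isotopologue envelopes, target lists, CID series.

Oligonucleotide fragments electrospray as multiply charged anions [M − zH]^z−;
m/z = (M + k·Δ¹³C − z·m_H+)/z with the proton mass (1.007276 Da, electron
mass included) and the averaged isotopologue spacing Δ¹³C = 1.003355 Da.
Target tables enumerate, per tRNA locus, one theoretical ion per wobble
modification state, charge and isotopologue — the machine-readable analog of
an XIC target list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem import (
    ElementalComposition,
    ISOTOPE_ABUNDANCE,
    ModRegistry,
    PROTON_MASS,
    WATER,
)
from .digestion import Fragment, ModifiedRNASequence, digest_rnase_t1, fragment_mass

__all__ = [
    "IonSpec",
    "CIDIon",
    "mz_negative",
    "isotope_envelope",
    "build_target_table",
    "target_table_to_tsv",
    "predict_cid_series",
    "ISOTOPOLOGUE_SPACING",
]

ISOTOPOLOGUE_SPACING = 1.0033548378  # ¹³C − ¹²C, averaged M+k spacing


def mz_negative(neutral_mass: float, z: int, k: int = 0) -> float:
    """m/z of the [M + k·Δ − zH]^z− anion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + k * ISOTOPOLOGUE_SPACING - z * PROTON_MASS) / z


@dataclass(frozen=True)
class IonSpec:
    """One theoretical XIC target: a fragment state at a charge and isotopologue."""

    seq_id: str
    start: int
    end: int
    state: str  # wobble residue code (or nucleoside code for nucleoside-level targets)
    z: int
    mz: float
    k: int = 0
    neutral_mass: float = 0.0
    three_prime: str = "linear_phosphate"
    mass_silent: bool = False

    @property
    def locus(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class CIDIon:
    series: str  # c, y, w, a-B
    index: int  # 1-based from the relevant terminus
    z: int
    mz: float
    neutral_mass: float


def isotope_envelope(comp: ElementalComposition, k_max: int) -> np.ndarray:
    """Relative isotopologue abundances M+0..M+k_max, normalized to M+0 = 1.

    Convolves per-element multinomial distributions over nominal mass shift;
    isotope-labelled atoms are fixed (they contribute no natural spread).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    dist = np.zeros(k_max + 1)
    dist[0] = 1.0
    for element, n in comp.natural_counts().items():
        iso = ISOTOPE_ABUNDANCE[element]
        poly = np.zeros(max(shift for shift, _ in iso) + 1)
        for shift, frac in iso:
            poly[shift] = frac
        # poly**n by repeated convolution, truncated to k_max+1 terms
        elem_dist = np.zeros(k_max + 1)
        elem_dist[0] = 1.0
        acc = poly.copy()
        m = n
        while m > 0:
            if m & 1:
                elem_dist = np.convolve(elem_dist, acc)[: k_max + 1]
            m >>= 1
            if m:
                acc = np.convolve(acc, acc)[: k_max + 1]
        dist = np.convolve(dist, elem_dist)[: k_max + 1]
    return dist / dist[0]


def anticodon_fragment(
    seq: ModifiedRNASequence,
    registry: ModRegistry,
    missed_cleavages: int = 0,
    three_prime_chem: str = "linear_phosphate",
) -> Fragment:
    """The digest fragment containing the annotated wobble position."""
    if seq.anticodon_index is None:
        raise ValueError(f"{seq.id}: no anticodon index annotated")
    for frag in digest_rnase_t1(seq, registry, missed_cleavages, three_prime_chem):
        if frag.missed_cleavages == missed_cleavages and frag.start <= seq.anticodon_index <= frag.end:
            return frag
    raise ValueError(f"{seq.id}: no fragment covers position {seq.anticodon_index}")


def build_target_table(
    trnas: Sequence[ModifiedRNASequence],
    wobble_states: dict[str, Sequence[str]],
    charges: Sequence[int],
    registry: ModRegistry,
    three_prime_chem: str = "linear_phosphate",
    k_max: int = 0,
) -> list[IonSpec]:
    """Theoretical ion list: one anticodon fragment per tRNA × state × charge × k.

    All states of a locus share fragment coordinates (hence phosphate count),
    the basis of the equal-ionization assumption behind peak-area ratios.
    """
    specs: list[IonSpec] = []
    for seq in trnas:
        states = wobble_states.get(seq.id)
        if not states:
            continue
        base_frag = anticodon_fragment(seq, registry, 0, three_prime_chem)
        wobble_offset = seq.anticodon_index - base_frag.start
        for state in states:
            definition = registry.get(state)
            residues = list(base_frag.residues)
            current = registry.get(residues[wobble_offset])
            if definition.parent != current.parent:
                raise ValueError(
                    f"{seq.id}: state {state!r} incompatible with wobble parent {current.parent}"
                )
            residues[wobble_offset] = state
            frag = replace(base_frag, residues=tuple(residues))
            mass = fragment_mass(frag, registry)
            for z in sorted(charges):
                for k in range(k_max + 1):
                    specs.append(
                        IonSpec(
                            seq_id=seq.id,
                            start=frag.start,
                            end=frag.end,
                            state=state,
                            z=z,
                            k=k,
                            mz=round(mz_negative(mass, z, k), 4),
                            neutral_mass=mass,
                            three_prime=frag.three_prime,
                            mass_silent=definition.mass_silent,
                        )
                    )
    specs.sort(key=lambda s: (s.seq_id, s.start, s.end, s.state, s.z, s.k))
    return specs


def target_table_to_tsv(specs: Sequence[IonSpec], path: Union[str, Path]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "locus": s.locus,
                "state_code": s.state,
                "z": s.z,
                "k": s.k,
                "mz_theor": f"{s.mz:.4f}",
                "three_prime_chem": s.three_prime,
            }
            for s in specs
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def _piece_mass(
    residues: Sequence[str],
    registry: ModRegistry,
    five_prime: str,
    three_prime: str,
) -> float:
    frag = Fragment(
        parent_id="_cid",
        start=1,
        end=len(residues),
        residues=tuple(residues),
        five_prime=five_prime,
        three_prime=three_prime,
    )
    return fragment_mass(frag, registry)


def predict_cid_series(
    frag: Fragment,
    registry: ModRegistry,
    series: Sequence[str] = ("c", "y", "w", "a-B"),
    z_max: int = 1,
) -> list[CIDIon]:
    """Theoretical CID backbone ions for an oligonucleotide fragment.

    c ions: 5' pieces ending in a 3'-phosphate; y ions: 3' pieces with 5'-OH
    (keeping the precursor's 3' chemistry); w ions: 3' pieces with
    5'-phosphate; a-B ions: 5' pieces with 3'-OH minus water and the 3'-terminal
    nucleobase.  Complementary c_i/y_{n−i} neutrals sum to the precursor
    neutral plus one water.
    """
    n = len(frag.residues)
    if n < 2:
        warnings.warn(f"fragment of length {n} yields no CID backbone ions")
        return []
    ions: list[CIDIon] = []
    for i in range(1, n):
        prefix = frag.residues[:i]
        suffix = frag.residues[i:]
        neutrals: dict[str, float] = {}
        if "c" in series:
            neutrals["c"] = _piece_mass(prefix, registry, frag.five_prime, "linear_phosphate")
        if "y" in series:
            neutrals["y"] = _piece_mass(suffix, registry, "OH", frag.three_prime)
        if "w" in series:
            neutrals["w"] = _piece_mass(suffix, registry, "phosphate", frag.three_prime)
        if "a-B" in series:
            base = registry.base_composition(prefix[-1]).mass()
            neutrals["a-B"] = (
                _piece_mass(prefix, registry, frag.five_prime, "OH") - WATER.mass() - base
            )
        for name, mass in neutrals.items():
            idx = i if name in ("c", "a-B") else n - i
            for z in range(1, z_max + 1):
                ions.append(CIDIon(name, idx, z, round(mz_negative(mass, z), 4), mass))
    ions.sort(key=lambda ion: (ion.series, ion.index, ion.z))
    return ions


def cid_to_tsv(ions: Sequence[CIDIon], path: Union[str, Path]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"series": i.series, "index": i.index, "z": i.z, "mz_theor": f"{i.mz:.4f}"}
            for i in ions
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
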