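"""Seeded generators for every input the pipeline consumes, with planted truth.

Three generators emulate the three experimental data streams:

* :func:`simulate_run` — a centroided negative-mode MS1 run in which each
  wobble-state ion of a locus elutes as a Gaussian peak whose noise-free
  integrated intensity equals ``total_abundance × planted frequency``, with
  ppm-level m/z jitter, multiplicative intensity noise and sparse baseline
  centroids.
* :func:`simulate_ortholog_matrix` — an ortholog presence/absence matrix with
  a planted pathway structure: "gap" organisms carrying downstream pathway
  families but no upstream hydroxylase, all carrying a planted bypass family,
  some with context evidence (proximity to an anchor or fusion), plus random
  decoy families.
* :func:`simulate_growth_reporter` — exponential growth curves with
  multiplicative lognormal noise and dual-luciferase counts with Poisson
  dispersion around planted F/R ratios.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem import ModRegistry, default_registry
from .digestion import ModifiedRNASequence
from .ions import IonSpec, isotope_envelope, build_target_table
from .mzml_io import Run, Scan, write_mzml
from .phyloprofile import GeneContext, OrthologMatrix

__all__ = [
    "SpectraSimConfig",
    "MatrixSimConfig",
    "GrowthReporterConfig",
    "simulate_run",
    "simulate_ortholog_matrix",
    "simulate_growth_reporter",
]


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# LC/MS run simulation
# --------------------------------------------------------------------------


@dataclass
class SpectraSimConfig:
    """Study conditions for one synthetic LC/MS run.

    ``targets`` lists the theoretical ions (several isotopologues/charges per
    state); ``frequencies`` maps locus id ("seq:start-end") → state → planted
    fraction.  Defaults approximate an Orbitrap-class nano-LC run: 0.1-min
    Gaussian peaks sampled every 0.03 min, 2-ppm centroid jitter, 5%
    multiplicative intensity noise and a sparse low-level baseline.
    """

    targets: Sequence[IonSpec]
    frequencies: dict[str, dict[str, float]]
    apex_rt: float = 12.0
    peak_sigma_min: float = 0.1
    total_abundance: float = 1e6
    mz_jitter_ppm: float = 2.0
    intensity_noise: float = 0.05  # lognormal sigma
    baseline_level: float = 500.0  # mean intensity of baseline centroids
    baseline_per_scan: int = 20
    scan_interval_min: float = 0.03
    rt_span_min: float = 4.0
    mz_range: tuple[float, float] = (600.0, 2000.0)
    seed: int = 0

    def validate(self) -> None:
        for locus, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"{locus}: frequencies sum to {total}, not 1")
        if self.peak_sigma_min <= 0 or self.scan_interval_min <= 0:
            raise SimulationError("peak sigma and scan interval must be positive")
        if min(self.mz_jitter_ppm, self.intensity_noise, self.baseline_level) < 0:
            raise SimulationError("noise levels must be non-negative")


def simulate_run(
    cfg: SpectraSimConfig,
    path: Union[str, Path],
    registry: Optional[ModRegistry] = None,
    envelopes: Optional[dict[tuple[str, str], np.ndarray]] = None,
) -> tuple[Run, pd.DataFrame]:
    """Write a synthetic centroided MS1 run and return (Run, truth table).

    Each state's ion cluster (its isotopologues at its charge) elutes as a
    Gaussian centred at ``apex_rt`` (staggered slightly per state so XICs show
    distinct peaks); noise-free, its summed scan intensities integrate to
    ``total_abundance × planted frequency`` per unit scan density.  With the
    same config and seed the mzML file is byte-identical.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_scans = int(round(cfg.rt_span_min / cfg.scan_interval_min)) + 1
    rts = cfg.apex_rt - cfg.rt_span_min / 2 + np.arange(n_scans) * cfg.scan_interval_min

    # group targets by locus and state
    groups: dict[str, dict[str, list[IonSpec]]] = {}
    for spec in cfg.targets:
        locus = f"{spec.seq_id}:{spec.start}-{spec.end}"
        groups.setdefault(locus, {}).setdefault(spec.state, []).append(spec)

    truth_rows = []
    peaks: list[tuple[float, float, float]] = []  # (mz, amplitude, apex_rt)
    for locus, freqs in cfg.frequencies.items():
        if locus not in groups:
            raise SimulationError(f"no targets supplied for locus {locus}")
        # apex offsets snapped to the scan grid so every state's peak is
        # sampled at the same phase (ratios then exact in the noise-free case)
        state_offsets = {
            state: round((i - (len(freqs) - 1) / 2) * 4 * cfg.peak_sigma_min / cfg.scan_interval_min)
            * cfg.scan_interval_min
            for i, state in enumerate(sorted(freqs))
        }
        for state, fraction in freqs.items():
            specs = groups[locus].get(state)
            if not specs:
                raise SimulationError(f"no targets for state {state!r} at {locus}")
            env = None
            if envelopes is not None:
                env = envelopes.get((locus, state))
            ks = sorted({s.k for s in specs})
            if env is None:
                env = np.array([1.0] + [0.0] * (len(ks) - 1))
            env = np.asarray(env, dtype=float)[: len(ks)]
            env = env / env.sum()
            apex = cfg.apex_rt + state_offsets[state]
            # scale so the Gaussian *area* in intensity·minutes is
            # total_abundance × fraction (all isotopologues combined)
            total_area = cfg.total_abundance * fraction
            for spec in specs:
                weight = env[ks.index(spec.k)]
                amplitude = total_area * weight / (cfg.peak_sigma_min * np.sqrt(2 * np.pi))
                peaks.append((spec.mz, amplitude, apex))
            truth_rows.append(
                {"locus": locus, "state": state, "fraction": fraction, "apex_rt": apex}
            )

    scans = []
    for rt in rts:
        mzs, intens = [], []
        for mz0, amplitude, apex in peaks:
            signal = amplitude * np.exp(-0.5 * ((rt - apex) / cfg.peak_sigma_min) ** 2)
            if signal < 1e-3 * amplitude or signal <= 0:
                continue
            if cfg.intensity_noise > 0:
                signal *= np.exp(rng.normal(0.0, cfg.intensity_noise))
            mz = mz0
            if cfg.mz_jitter_ppm > 0:
                mz *= 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6
            mzs.append(mz)
            intens.append(signal)
        if cfg.baseline_level > 0 and cfg.baseline_per_scan > 0:
            n_noise = cfg.baseline_per_scan
            mzs.extend(rng.uniform(*cfg.mz_range, size=n_noise))
            intens.extend(rng.exponential(cfg.baseline_level, size=n_noise))
        order = np.argsort(mzs) if mzs else np.array([], dtype=int)
        scans.append(Scan(rt=float(rt), mz=np.array(mzs)[order], intensity=np.array(intens)[order]))

    run = Run(scans=scans, polarity="negative", run_id=Path(path).stem)
    write_mzml(path, run)
    return run, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# Ortholog matrix simulation
# --------------------------------------------------------------------------


@dataclass
class MatrixSimConfig:
    """Planted-structure ortholog matrix emulating the bypass-gene screen.

    Pathway families follow the xo⁵U cast: an upstream hydroxylase family
    (``trhP``, with a two-gene variant ``trhP1``/``trhP2``) and downstream
    families (``cmoA``/``cmoB``, ``trmR``).  Gap organisms carry downstream
    families without any upstream family and always carry the bypass family.
    ``flip_noise`` applies to decoy cells only: it models ortholog-call error
    in the candidate background, not in the curated pathway annotations that
    define the query.
    """

    n_organisms: int = 60
    n_gap: int = 7
    n_decoys: int = 50
    background_rate: float = 0.3
    flip_noise: float = 0.0
    n_context_proximal: int = 2  # gap organisms with bypass near an anchor
    n_context_fused: int = 1  # gap organisms with bypass fused to an anchor
    bypass_family: str = "bypass"
    reference: str = "org_ref"
    must_also_have: tuple[str, ...] = ("org_bsub",)
    seed: int = 0

    PATHWAY = ("cmoA", "cmoB", "trmR", "trhP", "trhP1", "trhP2")

    def validate(self) -> None:
        if not (0 <= self.background_rate <= 1 and 0 <= self.flip_noise <= 1):
            raise SimulationError("rates must lie in [0, 1]")
        if self.n_gap < 1:
            raise SimulationError("need at least one gap organism")
        if self.n_gap + 2 > self.n_organisms:
            raise SimulationError("n_organisms too small for requested gap set")


#: query selecting the planted gap organisms (downstream present, upstream absent)
GAP_QUERY = "(cmoA & cmoB | trmR) & !trhP & !(trhP1 & trhP2)"


def simulate_ortholog_matrix(
    cfg: MatrixSimConfig,
) -> tuple[OrthologMatrix, list[GeneContext], dict]:
    """Generate (matrix, context table, truth record) with a planted bypass gene."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    families = list(cfg.PATHWAY) + [cfg.bypass_family] + [
        f"decoy{i:03d}" for i in range(cfg.n_decoys)
    ]
    special = [cfg.reference, *cfg.must_also_have]
    n_other = cfg.n_organisms - len(special) - cfg.n_gap
    if n_other < 0:
        raise SimulationError("n_organisms too small")
    gap_orgs = [f"org_gap{i:02d}" for i in range(cfg.n_gap)]
    other_orgs = [f"org{i:03d}" for i in range(n_other)]
    organisms = special + gap_orgs + other_orgs

    presence = pd.DataFrame(False, index=organisms, columns=families)
    # decoy background everywhere
    decoy_cols = [f for f in families if f.startswith("decoy")]
    presence.loc[:, decoy_cols] = rng.random((len(organisms), len(decoy_cols))) < cfg.background_rate

    # reference and must-also-have organisms: full pathway + bypass (curated genomes)
    for org in special:
        presence.loc[org, ["cmoA", "cmoB", "trmR", "trhP", cfg.bypass_family]] = True

    # gap organisms: downstream families, no upstream hydroxylase, bypass present
    for org in gap_orgs:
        mode = rng.integers(0, 3)  # 0: cmoAB, 1: trmR, 2: both
        if mode in (0, 2):
            presence.loc[org, ["cmoA", "cmoB"]] = True
        if mode in (1, 2):
            presence.loc[org, "trmR"] = True
        presence.loc[org, cfg.bypass_family] = True

    # other organisms: random pathway content that never matches the gap query
    for org in other_orgs:
        has_upstream = rng.random() < 0.6
        if has_upstream:
            if rng.random() < 0.5:
                presence.loc[org, "trhP"] = True
            else:
                presence.loc[org, ["trhP1", "trhP2"]] = True
            presence.loc[org, ["cmoA", "cmoB"]] = rng.random(2) < 0.7
            presence.loc[org, "trmR"] = rng.random() < 0.4
            presence.loc[org, cfg.bypass_family] = rng.random() < 0.5
        # organisms with no upstream family carry no downstream family either

    # flip noise on decoy cells only
    if cfg.flip_noise > 0:
        flips = rng.random((len(organisms), len(decoy_cols))) < cfg.flip_noise
        block = presence.loc[:, decoy_cols].to_numpy()
        presence.loc[:, decoy_cols] = np.where(flips, ~block, block)

    metadata = pd.DataFrame(
        {
            "organism_name": organisms,
            "lineage": ["planted_gap" if o in gap_orgs else "background" for o in organisms],
            "domain": "Bacteria",
        },
        index=organisms,
    )
    matrix = OrthologMatrix(presence, metadata)

    # context table: bypass near cmoA in some gap organisms, fused with trmR in others
    contexts: list[GeneContext] = []
    proximal = gap_orgs[: cfg.n_context_proximal]
    fused = gap_orgs[cfg.n_context_proximal : cfg.n_context_proximal + cfg.n_context_fused]
    for org in proximal:
        contexts.append(GeneContext(org, "cmoA", "chr1", 100_000, 101_000))
        contexts.append(GeneContext(org, cfg.bypass_family, "chr1", 102_000, 103_000))
    for org in fused:
        contexts.append(
            GeneContext(org, cfg.bypass_family, "chr1", 200_000, 202_000, fused_with="trmR")
        )
    # decoys get scattered, anchor-free context rows
    for i, fam in enumerate(decoy_cols[:10]):
        contexts.append(GeneContext(gap_orgs[i % len(gap_orgs)], fam, "chr2", 1_000 * (i + 1), 1_000 * (i + 1) + 500))

    annotation = {fam: "characterized" for fam in cfg.PATHWAY}
    annotation[cfg.bypass_family] = "uncharacterized"
    annotation.update({fam: "uncharacterized" for fam in decoy_cols})

    truth = {
        "bypass_family": cfg.bypass_family,
        "gap_organisms": gap_orgs,
        "query": GAP_QUERY,
        "reference": cfg.reference,
        "must_also_have": list(cfg.must_also_have),
        "annotation": annotation,
    }
    return matrix, contexts, truth


# --------------------------------------------------------------------------
# Growth / reporter simulation
# --------------------------------------------------------------------------


@dataclass
class GrowthReporterConfig:
    """Planted phenotype parameters: per-strain doubling times (minutes) and
    relative pausing ratios (F/R normalized to the first strain)."""

    doubling_times: dict[str, float] = field(
        default_factory=lambda: {"WT": 28.0, "dcmoB": 31.0, "dtrhPdtrhO": 38.0}
    )
    pausing_ratios: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "dcmoB": 2.0, "dtrhPdtrhO": 3.0}
    )
    od0: float = 0.05
    t_max_min: float = 240.0
    dt_min: float = 20.0
    od_noise: float = 0.02  # lognormal sigma on OD
    rluc_mean: float = 10_000.0
    base_fr: float = 0.1  # reference strain mean F/R
    n_replicates: int = 4
    poisson_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        if any(d <= 0 for d in self.doubling_times.values()):
            raise SimulationError("doubling times must be positive")
        if self.rluc_mean <= 0 or self.base_fr <= 0:
            raise SimulationError("reporter means must be positive")


def simulate_growth_reporter(
    cfg: GrowthReporterConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (growth CSV table, reporter CSV table, truth record)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = np.arange(0.0, cfg.t_max_min + 1e-9, cfg.dt_min)
    growth_rows = []
    for strain, td in cfg.doubling_times.items():
        od = cfg.od0 * np.power(2.0, times / td)
        if cfg.od_noise > 0:
            od = od * np.exp(rng.normal(0.0, cfg.od_noise, size=len(times)))
        for t, v in zip(times, od):
            growth_rows.append({"time": t, "od": v, "strain": strain})

    reporter_rows = []
    for strain, ratio in cfg.pausing_ratios.items():
        fluc_mean = ratio * cfg.base_fr * cfg.rluc_mean
        for rep in range(cfg.n_replicates):
            if cfg.poisson_counts:
                rluc = max(1.0, float(rng.poisson(cfg.rluc_mean)))
                fluc = float(rng.poisson(fluc_mean))
            else:
                rluc, fluc = cfg.rluc_mean, fluc_mean
            reporter_rows.append(
                {"strain": strain, "construct": "UCG", "fluc": fluc, "rluc": rluc}
            )

    truth = {
        "doubling_times": dict(cfg.doubling_times),
        "pausing_ratios": dict(cfg.pausing_ratios),
    }
    return pd.DataFrame(growth_rows), pd.DataFrame(reporter_rows), truth
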