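"""End-to-end pipelines: MS quantification and the phylogenomic screen.

Both pipelines are deterministic for fixed inputs/config, log every default
the analysis depends on (tolerance, end chemistry, test sidedness), and write
TSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .chem import ModRegistry, default_registry
from .digestion import read_annotated_fasta
from .ions import build_target_table, target_table_to_tsv
from .mzml_io import read_run
from .phyloprofile import (
    OrthologMatrix,
    contexts_from_tsv,
    context_rank,
    eval_query,
    fisher_cooccurrence,
    ProfileError,
    screen_bypass_candidates,
)
from .quantify import (
    DEFAULT_BOUNDARY_FRACTION,
    DEFAULT_MIN_SNR,
    DEFAULT_TOL_PPM,
    frequencies_to_tsv,
    modification_frequencies,
)

logger = logging.getLogger("rnashotgun")

__all__ = ["PipelineConfig", "run_ms_pipeline", "run_screen_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Options shared by the two pipelines; loadable from a YAML file."""

    registry_path: Optional[str] = None
    missed_cleavages: int = 0
    three_prime_chem: str = "linear_phosphate"
    charges: tuple[int, ...] = (1, 2)
    k_max: int = 2
    tol_ppm: float = DEFAULT_TOL_PPM
    min_snr: float = DEFAULT_MIN_SNR
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION
    sum_charges: bool = False
    query: str = ""
    proximity_bp: int = 5000
    fusion_bonus: int = 2
    fisher_sidedness: str = "two-sided"
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise PipelineError("config", f"unknown option {key!r}")
            if key == "charges":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def registry(self) -> ModRegistry:
        if self.registry_path:
            return ModRegistry.from_tsv(self.registry_path)
        return default_registry()


def run_ms_pipeline(
    config: PipelineConfig,
    fasta_path: Union[str, Path],
    mod_table_path: Optional[Union[str, Path]],
    wobble_states: dict[str, Sequence[str]],
    mzml_paths: Sequence[Union[str, Path]],
    output_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Digest → target table → XIC quantification across runs.

    Writes ``targets.tsv`` and ``frequencies.tsv`` in the output directory and
    returns the combined frequencies table.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = config.registry()
    logger.info(
        "MS pipeline: tol_ppm=%s min_snr=%s boundary_fraction=%s three_prime=%s mc=%d",
        config.tol_ppm, config.min_snr, config.boundary_fraction,
        config.three_prime_chem, config.missed_cleavages,
    )
    try:
        trnas = read_annotated_fasta(fasta_path, mod_table_path, registry)
    except FileNotFoundError as exc:
        raise PipelineError("parse", f"missing input file: {exc.filename}") from exc
    except Exception as exc:
        raise PipelineError("parse", str(exc)) from exc

    try:
        specs = build_target_table(
            trnas, wobble_states, config.charges, registry,
            three_prime_chem=config.three_prime_chem, k_max=config.k_max,
        )
    except Exception as exc:
        raise PipelineError("targets", str(exc)) from exc
    target_table_to_tsv(specs, out / "targets.tsv")
    logger.info("target table: %d ion specs", len(specs))

    loci = sorted({(s.seq_id, s.start, s.end) for s in specs})
    frames = []
    for mzml_path in mzml_paths:
        try:
            run = read_run(mzml_path)
        except Exception as exc:
            raise PipelineError("read_run", str(exc)) from exc
        results = []
        for seq_id, start, end in loci:
            locus_specs = [s for s in specs if (s.seq_id, s.start, s.end) == (seq_id, start, end)]
            try:
                res = modification_frequencies(
                    run, locus_specs,
                    tol_ppm=config.tol_ppm, min_snr=config.min_snr,
                    boundary_fraction=config.boundary_fraction,
                    sum_charges=config.sum_charges,
                )
            except Exception as exc:
                raise PipelineError("quantify", f"{seq_id}:{start}-{end}: {exc}") from exc
            results.append(res)
            logger.info("%s %s:%d-%d fractions=%s", run.run_id, seq_id, start, end,
                        {k: round(v, 4) for k, v in res.fractions.items()})
        frames.append(frequencies_to_tsv(results, run.run_id, out / f"frequencies_{run.run_id}.tsv"))
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    combined.to_csv(out / "frequencies.tsv", sep="\t", index=False)
    return combined


def run_screen_pipeline(
    config: PipelineConfig,
    matrix_path: Union[str, Path],
    context_path: Optional[Union[str, Path]],
    reference: str,
    must_also_have: Sequence[str] = (),
    annotation: Optional[dict[str, str]] = None,
    anchor_families: Sequence[str] = ("cmoA", "cmoB", "trmR"),
    fisher_pairs: Sequence[tuple[str, str]] = (),
    output_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Profile query → candidate intersection → context ranking → Fisher tests.

    Writes ``candidates.tsv`` and ``contingency.tsv``; returns the ranked
    candidate table.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "screen pipeline: query=%r proximity_bp=%d fusion_bonus=%d sidedness=%s",
        config.query, config.proximity_bp, config.fusion_bonus, config.fisher_sidedness,
    )
    try:
        matrix = OrthologMatrix.from_tsv(matrix_path)
    except FileNotFoundError as exc:
        raise PipelineError("matrix", f"missing input file: {exc.filename}") from exc
    try:
        selected = eval_query(matrix, config.query)
    except ProfileError as exc:
        raise PipelineError("query", str(exc)) from exc
    logger.info("query selected %d organisms: %s", len(selected), selected)
    if not selected:
        raise PipelineError("screen", "degenerate screen: query selected no organisms")
    try:
        pre, post = screen_bypass_candidates(matrix, selected, reference, must_also_have, annotation)
    except ProfileError as exc:
        raise PipelineError("screen", str(exc)) from exc
    logger.info("candidates: %d pre-filter, %d post-filter", len(pre), len(post))

    contexts = contexts_from_tsv(context_path) if context_path else []
    ranked = context_rank(post, contexts, set(anchor_families),
                          config.proximity_bp, config.fusion_bonus)
    cand_df = pd.DataFrame(
        [{"rank": i + 1, "family": fam, "score": score} for i, (fam, score) in enumerate(ranked)]
    )
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)

    fisher_rows = []
    for fam_a, fam_b in fisher_pairs:
        if fam_a == fam_b:
            raise PipelineError("fisher", f"self-pair ({fam_a}, {fam_b}) rejected")
        res = fisher_cooccurrence(matrix, fam_a, fam_b, config.fisher_sidedness)
        logger.info("fisher %s~%s: a=%d b=%d c=%d d=%d OR=%.3g p=%.3g",
                    fam_a, fam_b, res.a, res.b, res.c, res.d, res.odds_ratio, res.p_value)
        fisher_rows.append(
            {"family_a": fam_a, "family_b": fam_b, "a": res.a, "b": res.b, "c": res.c,
             "d": res.d, "odds_ratio": res.odds_ratio, "p_value": res.p_value,
             "sidedness": res.sidedness}
        )
    pd.DataFrame(fisher_rows).to_csv(out / "contingency.tsv", sep="\t", index=False)
    return cand_df
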