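"""Comparative-genomic bypass-gene screening over ortholog presence/absence matrices.

The screen formalizes pathway "gap filling": organisms that carry downstream
enzymes of a modification pathway (e.g. the carboxymethyl/methyl transferases
acting on ho⁵U34) but lack a known upstream enzyme must harbor an alternative
gene for the missing step.  A boolean profile query selects those gap
organisms; candidate families are the intersection of gene content across the
gap organisms plus reference genomes, filtered to uncharacterized annotation;
genomic context (proximity to pathway anchors, gene fusions) ranks the
survivors.  Exact Fisher tests quantify family co-occurrence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "OrthologMatrix",
    "GeneContext",
    "ContingencyResult",
    "parse_query",
    "eval_query",
    "screen_bypass_candidates",
    "context_rank",
    "fisher_cooccurrence",
    "fisher_from_counts",
    "fisher_enumerate",
]

METADATA_COLUMNS = ("organism_name", "lineage", "domain")


class ProfileError(ValueError):
    pass


class OrthologMatrix:
    """Boolean organisms × gene-families matrix with organism metadata."""

    def __init__(self, presence: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        if presence.index.duplicated().any():
            raise ProfileError("duplicate organism ids")
        if presence.columns.duplicated().any():
            raise ProfileError("duplicate family ids")
        self.presence = presence.astype(bool)
        if metadata is None:
            metadata = pd.DataFrame(index=presence.index)
        self.metadata = metadata.reindex(presence.index)

    @property
    def organisms(self) -> list[str]:
        return list(self.presence.index)

    @property
    def families(self) -> list[str]:
        return list(self.presence.columns)

    def has(self, family: str) -> pd.Series:
        if family not in self.presence.columns:
            raise ProfileError(f"unknown family {family!r}")
        return self.presence[family]

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path: Union[str, Path]) -> None:
        df = self.metadata.join(self.presence.astype(int))
        df.index.name = "organism_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "OrthologMatrix":
        df = pd.read_csv(path, sep="\t", index_col="organism_id")
        meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
        return cls(df.drop(columns=meta_cols).astype(int).astype(bool), df[meta_cols])


@dataclass(frozen=True)
class GeneContext:
    """One gene placement: coordinates on a replicon, optional fusion partner."""

    organism: str
    family: str
    replicon: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    fused_with: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ProfileError(f"{self.family}@{self.organism}: start > end")


def contexts_from_tsv(path: Union[str, Path]) -> list[GeneContext]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        fused = getattr(row, "fused_with", None)
        if pd.isna(fused) or fused == "":
            fused = None
        out.append(
            GeneContext(
                organism=row.organism,
                family=row.family,
                replicon=row.replicon,
                start=int(row.start),
                end=int(row.end),
                strand=getattr(row, "strand", "+"),
                fused_with=fused,
            )
        )
    return out


def contexts_to_tsv(contexts: Sequence[GeneContext], path: Union[str, Path]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "organism": c.organism,
                "family": c.family,
                "replicon": c.replicon,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "fused_with": c.fused_with or "",
            }
            for c in contexts
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


# --------------------------------------------------------------------------
# Query mini-language:  (cmoA & cmoB | trmR) & !trhP & !(trhP1 & trhP2)
# --------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\()|(\))|(&)|(\|)|(!)|([A-Za-z0-9_.\-]+))")


class _Parser:
    """Recursive descent for:  expr := term ('|' term)* ;
    term := factor ('&' factor)* ;  factor := '!' factor | '(' expr ')' | name"""

    def __init__(self, text: str):
        self.tokens = self._tokenize(text)
        self.pos = 0

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        tokens, pos = [], 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or m.end() == m.start():
                raise ProfileError(f"bad query syntax at offset {pos}: {text[pos:]!r}")
            tokens.append(next(g for g in m.groups() if g))
            pos = m.end()
        return tokens

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ProfileError("unexpected end of query")
        self.pos += 1
        return tok

    def parse(self):
        node = self._expr()
        if self._peek() is not None:
            raise ProfileError(f"trailing tokens in query: {self.tokens[self.pos:]}")
        return node

    def _expr(self):
        node = self._term()
        while self._peek() == "|":
            self._next()
            node = ("or", node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while self._peek() == "&":
            self._next()
            node = ("and", node, self._factor())
        return node

    def _factor(self):
        tok = self._next()
        if tok == "!":
            return ("not", self._factor())
        if tok == "(":
            node = self._expr()
            if self._next() != ")":
                raise ProfileError("unbalanced parenthesis in query")
            return node
        if tok in ("&", "|", ")"):
            raise ProfileError(f"unexpected {tok!r} in query")
        return ("has", tok)


def parse_query(text: str):
    """Parse the boolean mini-language into an expression tree."""
    return _Parser(text).parse()


def _eval_node(node, matrix: OrthologMatrix) -> pd.Series:
    op = node[0]
    if op == "has":
        return matrix.has(node[1])
    if op == "not":
        return ~_eval_node(node[1], matrix)
    if op == "and":
        return _eval_node(node[1], matrix) & _eval_node(node[2], matrix)
    if op == "or":
        return _eval_node(node[1], matrix) | _eval_node(node[2], matrix)
    raise ProfileError(f"unknown query node {op!r}")


def eval_query(matrix: OrthologMatrix, query: Union[str, tuple]) -> list[str]:
    """Organisms whose presence row satisfies the query, in matrix order."""
    node = parse_query(query) if isinstance(query, str) else query
    mask = _eval_node(node, matrix)
    return list(matrix.presence.index[mask])


# --------------------------------------------------------------------------
# Candidate screen and context ranking
# --------------------------------------------------------------------------


def screen_bypass_candidates(
    matrix: OrthologMatrix,
    selected: Sequence[str],
    reference: str,
    must_also_have: Sequence[str] = (),
    annotation: Optional[Mapping[str, str]] = None,
) -> tuple[list[str], list[str]]:
    """Families present in the reference, every selected (gap) organism, and
    every must-also-have organism; optionally filtered to uncharacterized ones.

    Returns (pre_filter, post_filter) lists in matrix column order.  An empty
    selected set is a degenerate screen and an error.
    """
    if not selected:
        raise ProfileError("degenerate screen: empty selected organism set")
    rows = [reference, *selected, *must_also_have]
    missing = [o for o in rows if o not in matrix.presence.index]
    if missing:
        raise ProfileError(f"organisms not in matrix: {missing}")
    mask = matrix.presence.loc[rows].all(axis=0)
    pre = list(matrix.presence.columns[mask])
    if annotation is None:
        return pre, list(pre)
    post = [f for f in pre if annotation.get(f, "characterized") == "uncharacterized"]
    return pre, post


def _interval_gap(a: GeneContext, b: GeneContext) -> int:
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0  # overlapping


def context_rank(
    candidates: Sequence[str],
    contexts: Sequence[GeneContext],
    anchor_families: set[str],
    proximity_bp: int = 5000,
    fusion_bonus: int = 2,
) -> list[tuple[str, int]]:
    """Rank candidates by genomic-context evidence.

    score = #organisms where the candidate lies within ``proximity_bp`` of an
    anchor on the same replicon + ``fusion_bonus`` × #organisms where it is
    fused with an anchor.  Descending score, ties broken lexicographically.
    """
    by_org: dict[str, list[GeneContext]] = {}
    for ctx in contexts:
        by_org.setdefault(ctx.organism, []).append(ctx)
    scores: dict[str, int] = {}
    for cand in candidates:
        near_orgs, fused_orgs = set(), set()
        for org, rows in by_org.items():
            cand_rows = [r for r in rows if r.family == cand]
            anchor_rows = [r for r in rows if r.family in anchor_families]
            for cr in cand_rows:
                if cr.fused_with in anchor_families:
                    fused_orgs.add(org)
                for ar in anchor_rows:
                    if ar.replicon == cr.replicon and _interval_gap(cr, ar) <= proximity_bp:
                        near_orgs.add(org)
        scores[cand] = len(near_orgs) + fusion_bonus * len(fused_orgs)
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


# --------------------------------------------------------------------------
# Exact co-occurrence statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyResult:
    a: int  # both families present
    b: int  # A only
    c: int  # B only
    d: int  # neither
    odds_ratio: float
    p_value: float
    sidedness: str

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_from_counts(
    a: int, b: int, c: int, d: int, sidedness: str = "two-sided"
) -> ContingencyResult:
    """Fisher's exact test on a 2×2 table.

    Two-sided p sums the probabilities of all same-margin tables no more
    likely than the observed one; one-sided ("greater") is the upper
    hypergeometric tail for positive association.  Odds ratio is the sample
    ad/bc, infinite when bc = 0.
    """
    if min(a, b, c, d) < 0:
        raise ProfileError("negative contingency counts")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}.get(sidedness)
    if alternative is None:
        raise ProfileError(f"unknown sidedness {sidedness!r}")
    _, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(a, b, c, d, odds, float(p), sidedness)


def fisher_cooccurrence(
    matrix: OrthologMatrix, fam_a: str, fam_b: str, sidedness: str = "two-sided"
) -> ContingencyResult:
    """Exact test of co-occurrence of two families across all organisms."""
    if fam_a == fam_b:
        raise ProfileError(f"self-pair {fam_a!r}: co-occurrence is undefined")
    pa, pb = matrix.has(fam_a), matrix.has(fam_b)
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    d = int((~pa & ~pb).sum())
    return fisher_from_counts(a, b, c, d, sidedness)


def fisher_enumerate(a: int, b: int, c: int, d: int, sidedness: str = "two-sided") -> float:
    """Independent oracle: exhaustive enumeration of all same-margin tables.

    Enumerates every table with the observed margins, computes each table's
    hypergeometric probability, and sums per the sidedness rule.  Used to
    cross-check :func:`fisher_from_counts`.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = math.comb(n, col1)
    probs = {
        x: math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    if sidedness == "two-sided":
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    if sidedness == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if sidedness == "less":
        return sum(p for x, p in probs.items() if x <= a)
    raise ProfileError(f"unknown sidedness {sidedness!r}")
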