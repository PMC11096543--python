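"""Gene expression to reaction activity scores (RAS).

A gene-protein-reaction (GPR) rule is a boolean expression over gene ids;
AND joins subunits of one enzyme complex and aggregates by the minimum
(limiting subunit), OR joins isozymes and aggregates by the sum (parallel
capacity).  Raw per-reaction aggregates are normalized to [0, 1] against the
99th percentile of positive aggregates; reactions without a GPR receive a
neutral score of 0.5 so the sampling bias neither rewards nor punishes them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .network import MetabolicNetwork

log = logging.getLogger(__name__)

NEUTRAL_SCORE = 0.5
SCORE_PERCENTILE = 99.0
PSEUDOBULK_SCALE = 1e4  # counts-per-10k normalization


@dataclass
class ExpressionProfile:
    """Per-gene expression levels for one sample (non-negative units)."""

    sample_id: str
    condition: str
    values: dict[str, float]

    def validate(self) -> None:
        bad = [g for g, x in self.values.items() if x < 0]
        if bad:
            raise ValidationError([f"negative expression for {g!r}" for g in bad])


@dataclass
class ReactionActivityScores:
    """Normalized [0,1] activity score per reaction, plus raw aggregates."""

    sample_id: str
    scores: dict[str, float]
    raw: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pseudo-bulk


def pseudobulk(counts: pd.DataFrame, cell_subset=None,
               scale: float = PSEUDOBULK_SCALE,
               sample_id: str = "pseudobulk", condition: str = "") -> ExpressionProfile:
    """Mean counts-per-``scale``-normalized expression over cells.

    ``counts`` is a genes x cells table; ``cell_subset`` optionally restricts
    to a list of cell barcodes (columns).
    """
    if counts.empty:
        raise ValidationError("empty count table")
    if cell_subset is not None:
        if len(cell_subset) == 0:
            raise ValidationError("empty cell subset")
        counts = counts[list(cell_subset)]
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("cell with zero total counts")
    norm = counts / totals * scale
    return ExpressionProfile(sample_id=sample_id, condition=condition,
                             values=norm.mean(axis=1).to_dict())


def read_mtx_counts(matrix_path, features_path, barcodes_path) -> pd.DataFrame:
    """Genes x cells counts from a MatrixMarket triplet + sidecar files
    (CellRanger layout: features/barcodes as first-column TSV)."""
    from scipy.io import mmread

    mat = mmread(str(matrix_path)).toarray()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(features)} features, {len(barcodes)} barcodes)"
        )
    return pd.DataFrame(mat, index=features, columns=barcodes)


def read_expression_csv(path) -> pd.DataFrame:
    """Plain gene x sample CSV (first column gene id)."""
    return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# GPR parsing: grammar  expr := term ('or' term)* ; term := factor ('and' factor)*
#                        factor := GENE | '(' expr ')'

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


class GprNode:
    """Node of a parsed GPR tree: op in {'gene','and','or'}."""

    __slots__ = ("op", "gene", "children")

    def __init__(self, op, gene=None, children=None):
        self.op = op
        self.gene = gene
        self.children = children or []

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        return set().union(*(c.genes() for c in self.children))

    def __repr__(self):
        if self.op == "gene":
            return self.gene
        return "(" + f" {self.op} ".join(map(repr, self.children)) + ")"


def _tokenize(rule: str):
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if not m:
            if rule[pos:].strip():
                raise FormatError(f"GPR parse error at position {pos}: {rule[pos:]!r}")
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a GPR rule into a boolean tree; None for an empty rule.

    Keywords ``and``/``or`` are case-insensitive; parentheses group.
    Malformed rules raise :class:`FormatError` with the offending position.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos][0].lower() if pos < len(tokens) else None

    def expect_factor() -> GprNode:
        nonlocal pos
        if pos >= len(tokens):
            raise FormatError(f"GPR parse error at end-of-input in {rule!r}")
        tok, at = tokens[pos]
        if tok == "(":
            pos += 1
            node = expr()
            if peek() != ")":
                raise FormatError(f"GPR parse error: unclosed '(' at position {at}")
            pos += 1
            return node
        if tok in {")"} or tok.lower() in {"and", "or"}:
            raise FormatError(f"GPR parse error: unexpected {tok!r} at position {at}")
        pos += 1
        return GprNode("gene", gene=tok)

    def term() -> GprNode:
        nonlocal pos
        node = expect_factor()
        children = [node]
        while peek() == "and":
            pos += 1
            children.append(expect_factor())
        return children[0] if len(children) == 1 else GprNode("and", children=children)

    def expr() -> GprNode:
        nonlocal pos
        children = [term()]
        while peek() == "or":
            pos += 1
            children.append(term())
        return children[0] if len(children) == 1 else GprNode("or", children=children)

    node = expr()
    if pos != len(tokens):
        tok, at = tokens[pos]
        raise FormatError(f"GPR parse error: trailing {tok!r} at position {at}")
    return node


def reaction_activity_score(tree: GprNode, profile: ExpressionProfile,
                            missing_default: float = 0.0) -> float:
    """Raw activity aggregate: AND -> min over subunits, OR -> sum of isozymes.

    Genes absent from the profile score ``missing_default`` (0 by default:
    absence of evidence treated as low activity) with a warning.
    """
    def ev(node: GprNode) -> float:
        if node.op == "gene":
            if node.gene not in profile.values:
                log.warning("gene %r missing from profile %s; scored %g",
                            node.gene, profile.sample_id, missing_default)
                return missing_default
            return float(profile.values[node.gene])
        vals = [ev(c) for c in node.children]
        return min(vals) if node.op == "and" else sum(vals)

    return ev(tree)


def raw_network_scores(net: MetabolicNetwork, profile: ExpressionProfile,
                       missing_default: float = 0.0) -> dict[str, float | None]:
    """Raw aggregate per enzymatic reaction; None marks empty GPRs.

    Exchange pseudo-reactions and the biomass reaction are not enzyme
    catalyzed and are excluded (they are constrained by measurements, not by
    transcript abundance).
    """
    out: dict[str, float | None] = {}
    for r in net.reactions:
        if r.is_exchange or r.id == net.biomass_reaction_id:
            continue
        tree = parse_gpr(r.gpr)
        out[r.id] = (
            None if tree is None
            else reaction_activity_score(tree, profile, missing_default)
        )
    return out


def normalize_scores(raw: dict[str, float | None],
                     sample_id: str = "sample",
                     neutral: float = NEUTRAL_SCORE,
                     percentile: float = SCORE_PERCENTILE) -> ReactionActivityScores:
    """Map raw aggregates to [0,1]: score = min(1, raw / P99 of positive raws).

    The percentile cap keeps one dominant transcript from flattening all
    other scores.  GPR-less reactions (raw None) get the neutral score; if
    every aggregate is zero all reactions fall back to neutral with a warning.
    """
    vals = [x for x in raw.values() if x is not None]
    if not vals:
        raise ValidationError("no scored reaction")
    positive = [x for x in vals if x > 0]
    if not positive:
        log.warning("all raw activity aggregates are zero; scores set to neutral")
        scores = {r: neutral for r in raw}
    else:
        p = float(np.percentile(positive, percentile))
        scores = {
            r: neutral if x is None else min(1.0, x / p) for r, x in raw.items()
        }
    return ReactionActivityScores(
        sample_id=sample_id, scores=scores,
        raw={r: (float("nan") if x is None else x) for r, x in raw.items()},
    )


def score_network(net: MetabolicNetwork, profile: ExpressionProfile,
                  missing_default: float = 0.0) -> ReactionActivityScores:
    """Full pipeline: GPR evaluation then percentile normalization."""
    return normalize_scores(raw_network_scores(net, profile, missing_default),
                            sample_id=profile.sample_id)


def write_scores_csv(path, ras: ReactionActivityScores) -> None:
    pd.DataFrame(
        {"reaction_id": list(ras.scores),
         "raw": [ras.raw.get(r, float("nan")) for r in ras.scores],
         "score": list(ras.scores.values())}
    ).to_csv(path, index=False)


def read_scores_csv(path, sample_id: str = "sample") -> ReactionActivityScores:
    df = pd.read_csv(path)
    return ReactionActivityScores(
        sample_id=sample_id,
        scores=dict(zip(df["reaction_id"], df["score"])),
        raw=dict(zip(df["reaction_id"], df["raw"])),
    )
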