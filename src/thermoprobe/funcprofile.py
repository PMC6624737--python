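"""Metagenome functional profiles: module completion, normalization,
and simulated-replicate differential calling.

KEGG-style module definitions are boolean expressions over KO (or CAZyme)
identifiers: at the top level, space-separated blocks are serial reaction
steps (AND); within a step, a comma separates alternatives (OR), a plus
joins obligatory members of a complex (AND), and a minus prefixes optional
members, which never block satisfaction.  The module completion ratio (MCR)
is the percentage of steps whose expression is satisfied by the KOs present.

Abundance and richness are normalized as counts per billion bases (cpb)
against the unassembled and assembled metagenome sizes respectively, then
log2-transformed with no pseudocount (zero counts keep a missing log value).

Differential calling follows the simulated-replicates scheme used when
metagenomes lack biological replication: technical replicates are drawn by
multinomial subsampling at a fraction of total depth with small uniform
jitter, the per-feature signal (M = log2 fold change, D = absolute
difference of normalized means) is compared against a noise cloud pooled
from all within-condition replicate pairs across features, and a feature is
called significant when the fraction of noise dominated by its signal
exceeds the probability threshold (default 0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


# -- module definition grammar ---------------------------------------------

@dataclass(frozen=True)
class Ko:
    name: str

    def to_text(self) -> str:
        return self.name


@dataclass(frozen=True)
class And:
    children: tuple
    sep: str = "+"  # '+' within a step, ' ' for nested step sequences

    def _wrap(self, c) -> str:
        if isinstance(c, Or) or (isinstance(c, And) and c.sep != self.sep):
            return f"({c.to_text()})"
        return c.to_text()

    def to_text(self) -> str:
        if self.sep == " ":
            return " ".join(self._wrap(c) for c in self.children)
        out = self._wrap(self.children[0])
        for c in self.children[1:]:
            if isinstance(c, Optional_):
                out += c.to_text()
            else:
                out += "+" + self._wrap(c)
        return out


@dataclass(frozen=True)
class Or:
    children: tuple

    def to_text(self) -> str:
        return ",".join(
            f"({c.to_text()})" if isinstance(c, And) and c.sep == " " else c.to_text()
            for c in self.children)


@dataclass(frozen=True)
class Optional_:
    child: object

    def to_text(self) -> str:
        inner = self.child.to_text()
        if isinstance(self.child, (And, Or)):
            inner = f"({inner})"
        return "-" + inner


class _Tokenizer:
    SYMBOLS = set("(),+- ")

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch in self.SYMBOLS:
                self.tokens.append((ch, i))
                i += 1
            elif ch.isalnum() or ch in "_.'":
                j = i
                while j < len(text) and (text[j].isalnum() or text[j] in "_.'"):
                    j += 1
                self.tokens.append((text[i:j], i))
                i = j
            else:
                raise ModuleParseError(f"unexpected character {ch!r}", i)
        self.tokens.append((None, len(text)))

    def peek(self):
        return self.tokens[self.pos][0]

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok


def _parse_seq(tz: _Tokenizer):
    """Space-separated sequence of OR-expressions (AND semantics)."""
    items = [_parse_or(tz)]
    while tz.peek() == " ":
        while tz.peek() == " ":
            tz.next()
        if tz.peek() in (None, ")"):
            break
        items.append(_parse_or(tz))
    return items[0] if len(items) == 1 else And(tuple(items), sep=" ")


def _parse_or(tz: _Tokenizer):
    items = [_parse_and(tz)]
    while tz.peek() == ",":
        tz.next()
        items.append(_parse_and(tz))
    return items[0] if len(items) == 1 else Or(tuple(items))


def _parse_and(tz: _Tokenizer):
    items = [_parse_atom(tz, optional=False)]
    while tz.peek() in ("+", "-"):
        sym, _ = tz.next()
        items.append(_parse_atom(tz, optional=(sym == "-")))
    return items[0] if len(items) == 1 else And(tuple(items), sep="+")


def _parse_atom(tz: _Tokenizer, optional: bool):
    tok, pos = tz.next()
    if tok == "-":
        node = _parse_atom(tz, optional=False)
        return Optional_(node if not isinstance(node, Optional_) else node.child)
    if tok == "(":
        node = _parse_seq(tz)
        closing, cpos = tz.next()
        if closing != ")":
            raise ModuleParseError("unbalanced parenthesis", cpos)
    elif tok is None or tok in _Tokenizer.SYMBOLS:
        raise ModuleParseError(f"expected identifier, got {tok!r}", pos)
    else:
        node = Ko(tok)
    return Optional_(node) if optional else node


@dataclass
class ModuleDefinition:
    """Parsed boolean step logic of a KEGG-style module."""

    module_id: str
    definition_text: str
    steps: list = field(repr=False)
    n_steps: int = 0

    def normalized(self) -> str:
        return " ".join(
            f"({s.to_text()})" if isinstance(s, And) and s.sep == " " else s.to_text()
            for s in self.steps)


def parse_module_definition(text: str, module_id: str = "") -> ModuleDefinition:
    """Parse a module DEFINITION string into its step tree."""
    text = text.strip()
    if not text:
        raise ModuleParseError("empty definition", 0)
    if text.count("(") != text.count(")"):
        raise ModuleParseError("unbalanced parentheses", len(text))
    tz = _Tokenizer(text)
    steps = []
    while tz.peek() is not None:
        while tz.peek() == " ":
            tz.next()
        if tz.peek() is None:
            break
        tok, pos = tz.tokens[tz.pos]
        if tok == "(":
            tz.next()
            node = _parse_seq(tz)
            closing, cpos = tz.next()
            if closing != ")":
                raise ModuleParseError("unbalanced parenthesis", cpos)
            # a trailing +/-/, binds the parenthesized group into one step
            if tz.peek() in ("+", "-", ","):
                node = _continue_step(tz, node)
        elif tok in (")", ",", "+"):
            raise ModuleParseError(f"unexpected {tok!r}", pos)
        elif tok == "-":
            tz.next()
            node = Optional_(_parse_atom(tz, optional=False))
            if tz.peek() in ("+", "-", ","):
                node = _continue_step(tz, node)
        else:
            node = _parse_or(tz)
        steps.append(node)
    if not steps:
        raise ModuleParseError("definition contains no steps", 0)
    return ModuleDefinition(module_id, text, steps, n_steps=len(steps))


def _continue_step(tz: _Tokenizer, node):
    items = [node]
    while tz.peek() in ("+", "-"):
        sym, _ = tz.next()
        items.append(_parse_atom(tz, optional=(sym == "-")))
    left = items[0] if len(items) == 1 else And(tuple(items), sep="+")
    if tz.peek() == ",":
        alts = [left]
        while tz.peek() == ",":
            tz.next()
            alts.append(_parse_and(tz))
        return Or(tuple(alts))
    return left


def _eval(node, present: frozenset):
    """Three-valued evaluation: True/False, or None for optional-only parts."""
    if isinstance(node, Ko):
        return node.name in present
    if isinstance(node, Optional_):
        return None
    if isinstance(node, And):
        vals = [_eval(c, present) for c in node.children]
        vals = [v for v in vals if v is not None]
        return all(vals) if vals else None
    if isinstance(node, Or):
        vals = [_eval(c, present) for c in node.children]
        vals = [v for v in vals if v is not None]
        return any(vals) if vals else None
    raise TypeError(node)


@dataclass
class McrResult:
    """Module completion ratio; Q-value is optional upstream metadata
    (a taxonomic-background feasibility statistic, never computed here)."""

    module_id: str
    satisfied_steps: int
    total_steps: int
    mcr: float
    q_value: float | None = None

    @property
    def biologically_feasible(self) -> bool | None:
        return None if self.q_value is None else self.q_value < 0.5


def mcr(module: ModuleDefinition, present_kos, q_value: float | None = None
        ) -> McrResult:
    """Module completion ratio: percent of mandatory steps satisfied.

    Optional (minus-prefixed) members never block satisfaction; steps that
    consist solely of optional members are excluded from both numerator and
    denominator.  Reported to one decimal place.
    """
    present = frozenset(present_kos)
    vals = [_eval(s, present) for s in module.steps]
    mandatory = [v for v in vals if v is not None]
    total = len(mandatory)
    satisfied = sum(mandatory)
    pct = round(100.0 * satisfied / total, 1) if total else 0.0
    return McrResult(module.module_id, satisfied, total, pct, q_value)


def read_module_definitions(path) -> list:
    """Read a module-per-line file: ``module_id<TAB>definition``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            mid, _, definition = line.partition("\t")
            out.append(parse_module_definition(definition, module_id=mid))
    return out


# -- normalization ----------------------------------------------------------

def normalize_counts(count, metagenome_bp):
    """Counts per billion bases and its log2.

    ``cpb = count / metagenome_bp * 1e9``.  Zero counts stay zero with a
    missing (NaN) log2 value — no pseudocount is added.
    """
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("negative count")
    if np.any(np.asarray(metagenome_bp) <= 0):
        raise ValueError("metagenome size must be positive")
    cpb = count / metagenome_bp * 1e9
    with np.errstate(divide="ignore"):
        log2 = np.where(cpb > 0, np.log2(np.maximum(cpb, 1e-300)), np.nan)
    if cpb.ndim == 0:
        return float(cpb), (float(log2) if cpb > 0 else math.nan)
    return cpb, log2


# -- differential calling ---------------------------------------------------

@dataclass
class DifferentialCall:
    feature: str
    mode: str
    m_stat: float
    d_stat: float
    probability: float
    significant: bool


def _simulate_replicates(counts: np.ndarray, nss: int, pnr: float, v: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Multinomial technical replicates at depth ~ U(pnr−v, pnr+v) of total."""
    total = counts.sum()
    probs = counts / total
    reps = np.empty((nss, len(counts)))
    for r in range(nss):
        depth = int(round(total * rng.uniform(pnr - v, pnr + v)))
        reps[r] = rng.multinomial(depth, probs)
    return reps


def differential_calls(counts_a: dict, counts_b: dict, sizes: tuple,
                       n_sim_replicates: int = 5, pnr: float = 0.2,
                       v: float = 0.02, threshold: float = 0.9,
                       seed: int = 0, mode: str = "abundance") -> list:
    """Differential features between two conditions via simulated replicates.

    ``sizes`` holds the (metagenome_bp_a, metagenome_bp_b) normalization
    denominators.  Deterministic given ``seed``.
    """
    features = sorted(set(counts_a) | set(counts_b))
    ca = np.array([counts_a.get(f, 0.0) for f in features], dtype=float)
    cb = np.array([counts_b.get(f, 0.0) for f in features], dtype=float)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("negative counts")
    size_a, size_b = sizes
    rng = np.random.default_rng(seed)

    if ca.sum() == 0 or cb.sum() == 0:
        return [DifferentialCall(f, mode, math.nan, math.nan, math.nan, False)
                for f in features]

    reps_a, _ = normalize_counts(
        _simulate_replicates(ca, n_sim_replicates, pnr, v, rng), size_a)
    reps_b, _ = normalize_counts(
        _simulate_replicates(cb, n_sim_replicates, pnr, v, rng), size_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_a = reps_a.mean(axis=0)
        mean_b = reps_b.mean(axis=0)
        m_sig = np.log2(mean_a / mean_b)
        d_sig = np.abs(mean_a - mean_b)

        noise_m, noise_d = [], []
        for reps in (reps_a, reps_b):
            for i in range(n_sim_replicates):
                for j in range(i + 1, n_sim_replicates):
                    noise_m.append(np.log2(reps[i] / reps[j]))
                    noise_d.append(np.abs(reps[i] - reps[j]))
    noise_m = np.concatenate(noise_m)
    noise_d = np.concatenate(noise_d)
    keep = ~np.isnan(noise_m)
    noise_m, noise_d = np.abs(noise_m[keep]), noise_d[keep]

    prob = np.full(len(features), np.nan)
    valid = ~np.isnan(m_sig)  # NaN signal: zero in both conditions' means
    n_noise = len(noise_m)
    idx = np.where(valid)[0]
    for start in range(0, len(idx), 256):
        sel = idx[start:start + 256]
        dominated = ((noise_m[None, :] <= np.abs(m_sig[sel])[:, None])
                     & (noise_d[None, :] <= d_sig[sel][:, None]))
        prob[sel] = dominated.sum(axis=1) / n_noise

    return [
        DifferentialCall(f, mode, float(m_sig[i]), float(d_sig[i]),
                         float(prob[i]),
                         bool(prob[i] > threshold) if not math.isnan(prob[i])
                         else False)
        for i, f in enumerate(features)
    ]


def differential_profile(inventories: pd.DataFrame, sample_a: str,
                         sample_b: str, sizes: dict, mode: str = "abundance",
                         **kwargs) -> pd.DataFrame:
    """Differential calls between two samples of an inventory table.

    ``inventories`` columns: sample_id, feature_id, estimated_copies,
    gene_count.  ``sizes`` maps sample_id to a dict with keys
    ``unassembled_bp`` and ``assembled_bp``; abundance mode uses estimated
    copies against unassembled size, richness mode uses distinct gene counts
    against assembled size.
    """
    col = "estimated_copies" if mode == "abundance" else "gene_count"
    size_key = "unassembled_bp" if mode == "abundance" else "assembled_bp"
    sub = inventories.set_index(["sample_id", "feature_id"])[col]
    counts_a = sub.loc[sample_a].to_dict()
    counts_b = sub.loc[sample_b].to_dict()
    calls = differential_calls(
        counts_a, counts_b, (sizes[sample_a][size_key], sizes[sample_b][size_key]),
        mode=mode, **kwargs)
    return pd.DataFrame([vars(c) for c in calls])
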