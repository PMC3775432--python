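"""Rule-based secondary-structure prediction by hydrophilic scan brackets.

The predictor walks the annotated sequence.  At each hydrophilic residue
``n_i`` a *scan bracket* opens; the following positions ``n_{i+1} ..
n_{i+6}`` are queried and the bracket closes at the first hydrophilic
residue among them.  If none of the six is hydrophilic the region is left
unstructured and scanning moves on.  A closed bracket is classified as an
alpha helix when the declarative rule set (a versioned YAML data file
encoding the balance of summed charge, charge product and summed
hydrophobicity against the blocking dielectric-displacement force) admits
it; helix regions span the whole bracket, endpoints included.

After the helix pass, every window of five consecutive still-unstructured
residues is tested against the beta-sheet inequalities

    Sigma |q_i| - Sigma h_i < 0.3     and     Sigma h_i > 0.1

(both sums over the 5-residue window by default; a narrower leading-pair
variant of the h-sum is selectable).  Accepted windows are labelled
E and the scan resumes after them.

Labels are {H, E, C}; region coordinates are 0-based inclusive internally
and 1-based in human-facing report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

import yaml

from .residue_props import AnnotatedSequence

__all__ = [
    "ScanBracket",
    "HelixRuleSet",
    "BetaRuleConfig",
    "SecondaryStructureAnnotation",
    "load_helix_rules",
    "open_helix_brackets",
    "evaluate_helix_bracket",
    "scan_beta_brackets",
    "evaluate_beta_bracket",
    "predict_secondary",
]

#: A bracket's closing hydrophilic residue must occur within this many
#: positions after the opening one.
SCAN_WINDOW = 6


@dataclass(frozen=True)
class ScanBracket:
    """A scan window between two hydrophilic residues (inclusive ends).

    ``sum_q``/``sum_h`` are charge/hydrophobicity sums over the configured
    domain (whole bracket by default); ``prod_q`` multiplies the charges of
    the intervening residues; ``q_intervening`` keeps the individual
    intervening charges for the single-residue rule conditions.
    """

    start: int
    end: int
    sum_q: float
    prod_q: float
    sum_h: float
    q_intervening: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("bracket end precedes start")

    @property
    def n_intervening(self) -> int:
        return self.end - self.start - 1


def bracket_from_sequence(
    seq: AnnotatedSequence,
    start: int,
    end: int,
    sum_domain: Literal["bracket", "intervening"] = "bracket",
) -> ScanBracket:
    """Build a :class:`ScanBracket` with sums taken over ``sum_domain``."""
    inner = range(start + 1, end)
    if sum_domain == "bracket":
        span = range(start, end + 1)
    elif sum_domain == "intervening":
        span = inner
    else:
        raise ValueError(f"unknown sum domain {sum_domain!r}")
    prod = 1.0
    for j in inner:
        prod *= seq.q[j]
    return ScanBracket(
        start=start,
        end=end,
        sum_q=sum(seq.q[i] for i in span),
        prod_q=prod if inner else 0.0,
        sum_h=sum(seq.h[i] for i in span),
        q_intervening=tuple(seq.q[j] for j in inner),
    )


# --------------------------------------------------------------------------
# Helix rule set (declarative, loaded from data)

_COMPARATORS = {
    "gt": lambda value, ref: value > ref,
    "lt": lambda value, ref: value < ref,
    "ge": lambda value, ref: value >= ref,
    "le": lambda value, ref: value <= ref,
    "abs_le": lambda value, ref: abs(value) <= ref,
}

_OBSERVABLES = ("sum_q", "abs_sum_q", "prod_q", "sum_h", "q_first", "q_all", "q_any_abs")


@dataclass(frozen=True)
class HelixRuleSet:
    """Declarative helix rules: per-n cases, each a list of alternative rows.

    A bracket with ``n`` intervening residues is a helix iff its case has a
    row whose conditions are all satisfied.  ``sum_domain`` records which
    residues the bracket sums must cover for the rules to mean what they
    say.
    """

    cases: tuple[tuple[tuple[int, ...], tuple[dict, ...]], ...]
    sum_domain: Literal["bracket", "intervening"] = "bracket"
    version: int = 1

    def __post_init__(self) -> None:
        for ns, _rows in self.cases:
            for n in ns:
                if not 1 <= n <= SCAN_WINDOW:
                    raise ValueError(f"rule case n={n} outside 1..{SCAN_WINDOW}")

    def rows_for(self, n: int) -> tuple[dict, ...]:
        for ns, rows in self.cases:
            if n in ns:
                return rows
        return ()


def load_helix_rules(path: str | None = None) -> HelixRuleSet:
    """Load the bundled rule file (or a user file with the same layout)."""
    if path is None:
        raw = (
            resources.files("driftfold.data").joinpath("helix_rules.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = yaml.safe_load(raw)
    cases = tuple(
        (tuple(case["n"]), tuple(case["rows"])) for case in doc["cases"]
    )
    return HelixRuleSet(
        cases=cases,
        sum_domain=doc.get("sum_domain", "bracket"),
        version=int(doc.get("version", 1)),
    )


_DEFAULT_RULES: HelixRuleSet | None = None


def default_helix_rules() -> HelixRuleSet:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_helix_rules()
    return _DEFAULT_RULES


def _row_matches(row: dict, b: ScanBracket) -> bool:
    for key, cond in row.items():
        if key == "q2_ne_q3":
            qi = b.q_intervening
            ok = len(qi) >= 2 and qi[0] != qi[1]
            if bool(cond) != ok:
                return False
            continue
        if key == "sum_q":
            value: float | None = b.sum_q
        elif key == "abs_sum_q":
            value = abs(b.sum_q)
        elif key == "prod_q":
            value = b.prod_q
        elif key == "sum_h":
            value = b.sum_h
        elif key == "q_first":
            value = b.q_intervening[0] if b.q_intervening else None
        elif key in ("q_all", "q_any_abs"):
            value = None  # handled below
        else:
            raise ValueError(f"unknown rule observable {key!r}")
        if key == "q_all":
            if not b.q_intervening:
                return False
            if not all(
                _COMPARATORS[op](q, ref)
                for op, ref in cond.items()
                for q in b.q_intervening
            ):
                return False
            continue
        if key == "q_any_abs":
            if not b.q_intervening:
                return False
            peak = max(abs(q) for q in b.q_intervening)
            if not all(_COMPARATORS[op](peak, ref) for op, ref in cond.items()):
                return False
            continue
        if value is None:
            return False
        if not all(_COMPARATORS[op](value, ref) for op, ref in cond.items()):
            return False
    return True


def evaluate_helix_bracket(
    b: ScanBracket, rules: HelixRuleSet | None = None
) -> Literal["helix", "none"]:
    """Classify one closed scan bracket against the helix rule set."""
    rules = rules or default_helix_rules()
    if b.n_intervening > SCAN_WINDOW:
        raise ValueError("helix bracket wider than the scan window")
    if b.n_intervening < 1:
        return "none"
    for row in rules.rows_for(b.n_intervening):
        if _row_matches(row, b):
            return "helix"
    return "none"


# --------------------------------------------------------------------------
# Scanning

def open_helix_brackets(
    seq: AnnotatedSequence,
    sum_domain: Literal["bracket", "intervening"] = "bracket",
) -> list[ScanBracket]:
    """Enumerate the scan brackets of the helix pass, in scan order.

    A bracket opens at every hydrophilic residue whose next hydrophilic
    neighbour lies within the following six positions; openers without a
    partner in the window produce no bracket.  Scanning resumes at a
    failed bracket's closing residue (every closed bracket is therefore
    reported once, whether or not it later classifies as a helix).
    """
    out: list[ScanBracket] = []
    n = len(seq)
    i = 0
    while i < n:
        if not seq.is_hydrophilic(i):
            i += 1
            continue
        close = None
        for j in range(i + 1, min(i + SCAN_WINDOW, n - 1) + 1):
            if seq.is_hydrophilic(j):
                close = j
                break
        if close is None:
            i += 1  # no partner within six: region unstructured, move on
            continue
        out.append(bracket_from_sequence(seq, i, close, sum_domain))
        i = close  # the closing residue may open the next bracket
    return out


@dataclass(frozen=True)
class BetaRuleConfig:
    """Beta-sheet inequality thresholds and the h-summation variant.

    ``sheet`` requires strictly  Sigma|q| - Sigma_h h < charge_margin  and
    Sigma_h h > h_floor  over a 5-residue window; ``h_span`` chooses whether
    the hydrophobicity sum runs over the whole window ("bracket", default)
    or only its leading pair ("leading_pair").
    """

    charge_margin: float = 0.3
    h_floor: float = 0.1
    h_span: Literal["bracket", "leading_pair"] = "bracket"


BETA_WINDOW = 5


def beta_bracket_from_sequence(
    seq: AnnotatedSequence, start: int, config: BetaRuleConfig | None = None
) -> ScanBracket:
    config = config or BetaRuleConfig()
    end = start + BETA_WINDOW - 1
    window = range(start, end + 1)
    h_span = window if config.h_span == "bracket" else range(start, start + 2)
    return ScanBracket(
        start=start,
        end=end,
        sum_q=sum(abs(seq.q[i]) for i in window),  # magnitude sum for beta
        prod_q=0.0,
        sum_h=sum(seq.h[i] for i in h_span),
    )


def evaluate_beta_bracket(
    b: ScanBracket, config: BetaRuleConfig | None = None
) -> Literal["sheet", "none"]:
    """Apply the two strict beta inequalities to a 5-residue bracket.

    ``b.sum_q`` must hold the summed charge *magnitudes* of the window.
    """
    config = config or BetaRuleConfig()
    if b.end - b.start + 1 != BETA_WINDOW:
        raise ValueError("beta bracket must span exactly 5 residues")
    if b.sum_q - b.sum_h < config.charge_margin and b.sum_h > config.h_floor:
        return "sheet"
    return "none"


def scan_beta_brackets(
    seq: AnnotatedSequence,
    labels: Sequence[str],
    config: BetaRuleConfig | None = None,
) -> list[ScanBracket]:
    """Enumerate candidate 5-residue beta windows over unstructured runs.

    Candidates are listed left-to-right; a window is a candidate only when
    all five residues are currently unstructured (label C).  This is the
    raw enumeration — the prediction pass itself accepts a window and then
    resumes after it (see :func:`predict_secondary`).
    """
    if len(labels) != len(seq):
        raise ValueError("labels must align with the sequence")
    out = []
    for start in range(0, len(seq) - BETA_WINDOW + 1):
        if all(labels[start + k] == "C" for k in range(BETA_WINDOW)):
            out.append(beta_bracket_from_sequence(seq, start, config))
    return out


@dataclass(frozen=True)
class SecondaryStructureAnnotation:
    """Per-residue H/E/C labels plus the ordered structured-region list."""

    labels: str
    regions: tuple[tuple[int, int, str], ...]  # (start, end, kind), 0-based incl.

    def __post_init__(self) -> None:
        covered = set()
        for start, end, kind in self.regions:
            if kind not in ("H", "E"):
                raise ValueError(f"region kind must be H or E, got {kind!r}")
            for i in range(start, end + 1):
                if i in covered:
                    raise ValueError("structured regions overlap")
                covered.add(i)
                if self.labels[i] != kind:
                    raise ValueError("region list inconsistent with labels")
        if covered != {i for i, c in enumerate(self.labels) if c != "C"}:
            raise ValueError("regions must tile the non-C labels exactly")

    def __len__(self) -> int:
        return len(self.labels)

    def region_table(self) -> list[tuple[int, int, str]]:
        """Regions with 1-based inclusive coordinates, for reports."""
        return [(s + 1, e + 1, kind) for s, e, kind in self.regions]


def predict_secondary(
    seq: AnnotatedSequence,
    rules: HelixRuleSet | None = None,
    beta: BetaRuleConfig | None = None,
) -> SecondaryStructureAnnotation:
    """Full two-pass prediction: helix scan first, then beta windows.

    The helix pass labels every accepted bracket H, endpoints included,
    and resumes scanning after it; a rejected bracket's closing residue
    may open the next bracket.  The beta pass then slides a 5-residue
    window over the remaining all-C runs, labelling accepted windows E and
    resuming after them.  The function is pure, hence idempotent in the
    sense that re-predicting the same sequence reproduces the labels.
    """
    rules = rules or default_helix_rules()
    beta = beta or BetaRuleConfig()
    n = len(seq)
    labels = ["C"] * n
    regions: list[tuple[int, int, str]] = []

    i = 0
    while i < n:
        if not seq.is_hydrophilic(i):
            i += 1
            continue
        close = None
        for j in range(i + 1, min(i + SCAN_WINDOW, n - 1) + 1):
            if seq.is_hydrophilic(j):
                close = j
                break
        if close is None:
            i += 1
            continue
        b = bracket_from_sequence(seq, i, close, rules.sum_domain)
        if evaluate_helix_bracket(b, rules) == "helix":
            for k in range(i, close + 1):
                labels[k] = "H"
            regions.append((i, close, "H"))
            i = close + 1
        else:
            i = close

    i = 0
    while i <= n - BETA_WINDOW:
        if all(labels[i + k] == "C" for k in range(BETA_WINDOW)):
            b = beta_bracket_from_sequence(seq, i, beta)
            if evaluate_beta_bracket(b, beta) == "sheet":
                for k in range(BETA_WINDOW):
                    labels[i + k] = "E"
                regions.append((i, i + BETA_WINDOW - 1, "E"))
                i += BETA_WINDOW
                continue
        i += 1

    regions.sort()
    return SecondaryStructureAnnotation(labels="".join(labels), regions=tuple(regions))
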