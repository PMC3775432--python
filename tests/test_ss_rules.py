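import itertools

import pytest

from driftfold.residue_props import annotate_sequence, default_table
from driftfold.ss_rules import (
    BetaRuleConfig,
    ScanBracket,
    beta_bracket_from_sequence,
    bracket_from_sequence,
    default_helix_rules,
    evaluate_beta_bracket,
    evaluate_helix_bracket,
    load_helix_rules,
    open_helix_brackets,
    predict_secondary,
    scan_beta_brackets,
)

from oracles import direct_scan_labels


def _bracket(n, sum_q=0.0, prod_q=0.0, sum_h=0.0, qi=None):
    return ScanBracket(
        start=0,
        end=n + 1,
        sum_q=sum_q,
        prod_q=prod_q,
        sum_h=sum_h,
        q_intervening=tuple(qi) if qi is not None else (0.1,) * n,
    )


# ----------------------------------------------------------- helix scan

def test_all_hydrophobic_sequence_opens_no_brackets():
    seq = annotate_sequence("AILVAILVAI")
    assert open_helix_brackets(seq) == []


def test_bracket_between_hydrophilic_pair_within_window():
    # hydrophilic at 0 and 3, hydrophobic between
    seq = annotate_sequence("SAAS")
    (b,) = open_helix_brackets(seq)
    assert (b.start, b.end, b.n_intervening) == (0, 3, 2)


def test_no_partner_within_six_leaves_region_unstructured():
    # hydrophilic at 0, next hydrophilic at 8 (> 6 positions away)
    seq = annotate_sequence("SAAAAAAAS")
    brackets = open_helix_brackets(seq)
    assert all(b.start != 0 for b in brackets) and len(brackets) == 0


def test_scan_resumes_at_closing_residue():
    # hydrophilic at 0, 2, 4: brackets (0,2) and (2,4)
    seq = annotate_sequence("SASAS")
    spans = [(b.start, b.end) for b in open_helix_brackets(seq)]
    assert spans == [(0, 2), (2, 4)]


# ------------------------------------------------------- helix rule set

def test_rule_n1_small_positive_sum_with_positive_product_is_helix():
    b = _bracket(1, sum_q=0.1, prod_q=0.05, sum_h=2.0, qi=[0.05])
    assert evaluate_helix_bracket(b) == "helix"


def test_rule_n1_strongly_negative_sum_with_zero_product_is_helix():
    b = _bracket(1, sum_q=-2.0, prod_q=0.0, sum_h=-5.0, qi=[0.0])
    assert evaluate_helix_bracket(b) == "helix"


def test_rule_n1_outside_every_row_is_none():
    # exhaustive check of the encoded n=1 rows on a value no row accepts:
    # sum_q in dead zone, product negative-but-sum-too-small, first charge
    # small, sum_h large positive
    b = _bracket(1, sum_q=0.05, prod_q=-0.01, sum_h=8.0, qi=[0.05])
    assert evaluate_helix_bracket(b) == "none"


def test_rule_strongly_charged_intervening_blocks_helix():
    # n=1 bracket that would pass the small-positive row, except the
    # intervening charge pushes sum_q out of every window
    b = _bracket(1, sum_q=1.1, prod_q=1.0, sum_h=2.0, qi=[1.0])
    assert evaluate_helix_bracket(b) == "none"


def test_rule_zero_intervening_is_never_helix():
    b = ScanBracket(start=0, end=1, sum_q=-2.0, prod_q=0.0, sum_h=-7.0)
    assert evaluate_helix_bracket(b) == "none"


def test_even_n_falls_back_to_nearest_smaller_case():
    b2 = _bracket(2, sum_q=0.1, prod_q=0.01, sum_h=2.0, qi=[0.1, 0.1])
    b1 = _bracket(1, sum_q=0.1, prod_q=0.01, sum_h=2.0, qi=[0.1])
    assert evaluate_helix_bracket(b2) == evaluate_helix_bracket(b1) == "helix"


def test_charged_mutation_never_leaves_helix_on_hydrophobic_interiors():
    """Grid enumeration: for every n=1 bracket that is helix-positive via
    the small-positive-charge row (0 < sum_q < 0.2, prod_q > 0), adding
    |q| >= 0.9 to the intervening residue always breaks the helix, as
    long as the bracket is not strongly hydrophilic (sum_h >= -0.3)."""
    rules = default_helix_rules()
    q1s = [round(0.005 + 0.01 * k, 3) for k in range(100)]  # (0, 1)
    hs = [-0.3, -0.2, 0.0, 1.0, 4.0, 9.0]
    survivors = []
    for q1 in q1s:
        for qe in (-0.95, -0.5, -0.1, 0.0, 0.1):  # summed endpoint charge
            sq = qe + q1
            for sh in hs:
                base = _bracket(1, sum_q=sq, prod_q=q1, sum_h=sh, qi=[q1])
                if not (0.0 < sq < 0.2):
                    continue
                if evaluate_helix_bracket(base, rules) != "helix":
                    continue
                for dq in (-1.0, -0.9, 0.9, 1.0):
                    q1m = q1 + dq
                    mut = _bracket(
                        1, sum_q=qe + q1m, prod_q=q1m, sum_h=sh, qi=[q1m]
                    )
                    if evaluate_helix_bracket(mut, rules) == "helix":
                        survivors.append((q1, qe, sh, dq))
    assert survivors == []


# ------------------------------------------------------------ beta rule

def test_beta_rule_accepts_interior_point():
    b = ScanBracket(start=0, end=4, sum_q=0.1, prod_q=0.0, sum_h=0.15)
    assert evaluate_beta_bracket(b) == "sheet"


@pytest.mark.parametrize(
    "sum_q,sum_h",
    [
        (0.5, 0.2),  # sum|q| - sum_h = 0.3 exactly -> not sheet
        (0.0, 0.1),  # sum_h = 0.1 exactly -> not sheet
    ],
)
def test_beta_rule_strict_boundaries_rejected(sum_q, sum_h):
    b = ScanBracket(start=0, end=4, sum_q=sum_q, prod_q=0.0, sum_h=sum_h)
    assert evaluate_beta_bracket(b) == "none"


def test_beta_bracket_must_span_five_residues():
    with pytest.raises(ValueError):
        evaluate_beta_bracket(ScanBracket(0, 3, 0.0, 0.0, 1.0))


def test_scan_beta_brackets_enumeration():
    seq = annotate_sequence("AAAAAA")
    assert scan_beta_brackets(seq, "HHHHHH") == []
    assert [b.start for b in scan_beta_brackets(seq, "CCCCCC")] == [0, 1]
    (b,) = scan_beta_brackets(annotate_sequence("AAAAA"), "CCCCC")
    assert (b.start, b.end) == (0, 4)


def test_beta_leading_pair_variant_changes_h_sum():
    seq = annotate_sequence("AVLAI")
    full = beta_bracket_from_sequence(seq, 0)
    pair = beta_bracket_from_sequence(
        seq, 0, BetaRuleConfig(h_span="leading_pair")
    )
    assert full.sum_h == pytest.approx(sum(seq.h))
    assert pair.sum_h == pytest.approx(seq.h[0] + seq.h[1])


# -------------------------------------------------------- full predict

def test_helix_former_fixture_has_helix_region():
    ann = predict_secondary(annotate_sequence("AAAADAEAAAAA"))
    assert (4, 6, "H") in ann.regions
    assert ann.labels[4:7] == "HHH"


@pytest.mark.parametrize("mutant", ["K", "D"])
def test_charged_mutation_dissolves_helix(mutant):
    base = predict_secondary(annotate_sequence("AAAADAEAAAAA"))
    assert "H" in base.labels
    mutated = "AAAAD" + mutant + "EAAAAA"
    ann = predict_secondary(annotate_sequence(mutated))
    assert "H" not in ann.labels


def test_labels_partition_and_regions_tile():
    ann = predict_secondary(annotate_sequence("KAAKAAVLAIAVLAIAAEAAE"))
    assert len(ann.labels) == 21
    structured = {i for s, e, _ in ann.regions for i in range(s, e + 1)}
    assert structured == {i for i, c in enumerate(ann.labels) if c != "C"}


def test_predict_is_idempotent_pure():
    seq = annotate_sequence("KAAKAAVLAIAVLAIAAEAAE")
    assert predict_secondary(seq).labels == predict_secondary(seq).labels


def test_helix_regions_start_on_hydrophilic_residue():
    seq = annotate_sequence("AAAADAEAAADAEAA")
    ann = predict_secondary(seq)
    for s, _e, kind in ann.regions:
        if kind == "H":
            assert seq.is_hydrophilic(s)


def test_matches_direct_scan_oracle_on_handpicked_sequences():
    for letters in ["AAAADAEAAAAA", "KAAKAAVLAIAVLAIAAEAAE", "SASAS",
                    "DDDDDDDD", "AVLAIAVLAI", "SAKDAEAHSA"]:
        seq = annotate_sequence(letters)
        expected = direct_scan_labels(
            seq.q, seq.h, [seq.is_hydrophilic(i) for i in range(len(seq))]
        )
        assert predict_secondary(seq).labels == expected, letters


def test_rule_file_roundtrip(tmp_path):
    import yaml

    rules = default_helix_rules()
    alt = tmp_path / "rules.yaml"
    alt.write_text(
        yaml.safe_dump(
            {
                "version": 99,
                "sum_domain": "intervening",
                "cases": [{"n": [1], "rows": [{"sum_q": {"gt": 0.5}}]}],
            }
        )
    )
    loaded = load_helix_rules(str(alt))
    assert loaded.version == 99 and loaded.sum_domain == "intervening"
    b = _bracket(1, sum_q=0.6, prod_q=0.1, qi=[0.6])
    assert evaluate_helix_bracket(b, loaded) == "helix"
    assert rules.sum_domain == "bracket"
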