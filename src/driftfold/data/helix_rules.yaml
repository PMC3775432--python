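# Declarative alpha-helix rule set for hydrophilic-bracket scan windows.
#
# A scan bracket opens at a hydrophilic residue and closes at the next
# hydrophilic residue found within the following six positions; n is the
# number of intervening (hydrophobic) residues, 1..6.  A bracket is a helix
# iff, for the case matching its n, ANY row has ALL of its conditions true.
#
# Observables a row may reference:
#   sum_q      Sigma q_i over the bracket (endpoints + intervening), in e
#              (over intervening only when sum_domain = "intervening")
#   abs_sum_q  |sum_q|
#   prod_q     Pi q_j over the intervening residues
#   sum_h      Sigma h_i, same domain as sum_q
#   q_first    charge of the first intervening residue
#   q_all      predicate applied to EVERY intervening charge
#   q_any_abs  predicate applied to max_j |q_j| over intervening residues
#   q2_ne_q3   true when the first two intervening charges differ
#
# Comparators: gt / lt / ge / le (strict unless named otherwise), and
# abs_le for "equals zero" tests on products of floating charges.
#
# Encoding notes (this is the default, versioned reading of the rules;
# alternative readings belong in a copy of this file, not in code):
#   * Explicit cases exist for n = 1, 3, 5 only; even n fall back to the
#     nearest smaller case (2->1, 4->3, 6->5).
#   * The fourth n=1 row pairs a negative charge product with a small
#     positive sum window, 0.1 < a < 0.5.
#   * The n=5 individual-charge rows mean "all intervening q > 0" and
#     "some intervening |q| > 0.6" respectively.
version: 1
sum_domain: bracket          # "bracket" | "intervening"
cases:
  - n: [1, 2]
    rows:
      - sum_q: {gt: 0.0, lt: 0.2}
        prod_q: {gt: 0.0}
      - sum_q: {lt: -0.5}
        prod_q: {abs_le: 1.0e-12}
      - q_first: {gt: 0.9}
        sum_h: {lt: -0.3}
      - sum_q: {gt: 0.1, lt: 0.5}
        prod_q: {lt: 0.0}
  - n: [3, 4]
    rows:
      - sum_q: {gt: 1.0}
        q2_ne_q3: true
      - abs_sum_q: {lt: 0.5}
        sum_h: {lt: -6.0}
  - n: [5, 6]
    rows:
      - sum_q: {gt: 0.3, lt: 0.5}
      - abs_sum_q: {gt: 1.0}
      - q_all: {gt: 0.0}
      - q_any_abs: {gt: 0.6}
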