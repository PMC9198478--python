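"""Certify which truth tables a single weighted threshold can realise.

A function f on {0,1}^n is linearly separable when some weights w and
threshold Theta give f(X) = 1 iff w.X >= Theta.  AND is; the compact
feature-binding table and XOR are not.  For the feature-binding table the
pairing argument gives a human-readable proof: adding the two 0-row
constraints bounds w1+w2+w3+w4 by 2*Theta, adding the two 1-row
constraints forces it above 2*Theta.
"""

from sifneuron import (
    find_pairing_certificate,
    is_linearly_separable,
    make_and,
    make_cfbp,
    make_xor,
)

for name, table in [("AND", make_and()), ("XOR", make_xor()), ("cFBP", make_cfbp(2))]:
    lp = is_linearly_separable(table, method="lp")
    ex = is_linearly_separable(table, method="exhaustive")
    verdict = "separable" if lp.separable else "NOT separable"
    print(f"{name:>4}: {verdict} (lp and exhaustive agree: {lp.separable == ex.separable})")
    if lp.separable:
        print(f"      integer witness: w = {ex.weights}, theta = {ex.theta}")
    pairing = find_pairing_certificate(table)
    if pairing is not None:
        z = [" ".join(map(str, p)) for p in pairing.zero_rows]
        o = [" ".join(map(str, p)) for p in pairing.one_rows]
        print(f"      pairing proof: 0-rows {z} and 1-rows {o} cover the same inputs")
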