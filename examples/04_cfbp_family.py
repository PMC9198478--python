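"""The feature-binding problem generalises beyond four inputs.

With 2m inputs split into two clusters of m, activating a whole cluster
(an m-tuple) must output 0 while two complementary straddling m-tuples
must output 1.  Every member of the family is linearly inseparable, and
the same pairing proof applies.
"""

from sifneuron import check_pairing_contradiction, is_linearly_separable, make_cfbp

for m in (2, 3, 4):
    table = make_cfbp(m)
    cert = is_linearly_separable(table, method="lp")
    print(f"m = {m} ({table.n_inputs} inputs):")
    for pattern, output in table.rows:
        print(f"  {''.join(map(str, pattern))} -> {output}")
    print(
        f"  linearly separable: {cert.separable}; "
        f"pairing contradiction: {check_pairing_contradiction(table)}"
    )
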