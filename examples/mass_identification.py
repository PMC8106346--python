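"""Worked mass identification: is observed m/z 523.1232 consistent with baumin?

Computes the theoretical protonated-adduct m/z of the styrylpyrone baumin
(C27H22O11), differences it against the observed feature m/z, and then
enumerates every CHNO formula within 0.5 mDa to show the call is unique
under realistic element bounds.
"""

from npomics.masscalc import find_formulas, mass_error, parse_formula

observed = 523.1232
formula = parse_formula("C27H22O11")

err = mass_error(observed, formula, "[M+H]+")
print(err.report())
# A |error| well under 1 mDa (sub-ppm) at m/z 523 is instrument-grade
# agreement: the formula is mass-consistent with the observed feature.

candidates = find_formulas(observed, "[M+H]+", tol_mda=0.5,
                           element_bounds={"C": 40, "H": 60, "O": 15, "N": 5})
print(f"\nformulas within 0.5 mDa (C<=40 H<=60 O<=15 N<=5): {len(candidates)}")
for f, delta in candidates:
    print(f"  {str(f):>14}  {delta:+.3f} mDa")
# Each line is a candidate neutral formula and its mass error; the planted
# answer C27H22O11 should rank at (or near) the top.
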