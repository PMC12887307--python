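"""Monoisotopic masses and ionization constants.

All masses in Da, from the standard atomic-mass tables, kept in one place so
every module (generation, assignment, binning) agrees to the last digit.
"""

MASS_C = 12.0
MASS_H = 1.0078250319
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_S = 31.97207069

#: Mass removed on deprotonation ([M-H]-): a proton (H minus its electron).
PROTON_MASS = 1.00727646677


def neutral_mass(c: int, h: int, n: int, o: int, s: int) -> float:
    """Monoisotopic mass of the neutral formula C_c H_h N_n O_o S_s."""
    return c * MASS_C + h * MASS_H + n * MASS_N + o * MASS_O + s * MASS_S


def deprotonated_mz(c: int, h: int, n: int, o: int, s: int) -> float:
    """Theoretical m/z of the singly charged [M-H]- ion."""
    return neutral_mass(c, h, n, o, s) - PROTON_MASS
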