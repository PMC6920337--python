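"""Nearest-neighbour melting temperatures for short anchored primers.

Implements the unified nearest-neighbour model (SantaLucia & Hicks 2004
parameter set) with the Owczarzy monovalent/magnesium salt correction.
Primer candidates are screened downstream against length-dependent Tm
thresholds (e.g. >= 38 degC for 12-mers, >= 50 degC for 16-mers), so the
absolute parameterization matters less than its consistency; all ionic
conditions are exposed as configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqmodel import revcomp

R_GAS = 1.987  # cal / (mol K)

# SantaLucia & Hicks (2004) unified Watson-Crick parameters:
# dinucleotide -> (dH kcal/mol, dS cal/mol/K), 5'->3' top strand.
NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# complete the table via reverse-complement symmetry (TT = AA, etc.)
for _k, _v in list(NN_DH_DS.items()):
    NN_DH_DS.setdefault(revcomp(_k), _v)

INITIATION = (0.2, -5.7)
TERMINAL_AT_PENALTY = (2.2, 6.9)
SYMMETRY_DS = -1.4  # self-complementary duplexes only


@dataclass
class ThermoParams:
    """Ionic conditions and strand concentration for the Tm calculation.

    Defaults are generic PCR-like conditions: 50 mM monovalent cation,
    1.5 mM total Mg2+, 0.2 mM dNTPs (which chelate Mg2+), 200 nM primer
    in excess over template.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.2
    primer_conc_nM: float = 200.0
    nn_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: NN_DH_DS
    )

    def __post_init__(self):
        if self.primer_conc_nM <= 0:
            raise ValueError("primer concentration must be > 0")
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table missing dinucleotides: {sorted(missing)}")


DEFAULT_PARAMS = ThermoParams()


def _owczarzy_inverse_tm_correction(
    seq: str, mon_mM: float, mg_mM: float, dntp_mM: float
) -> float:
    """1/Tm correction term (1/K) for monovalent + Mg2+ conditions.

    Follows the Owczarzy et al. (2008) decision tree: free Mg2+ after dNTP
    chelation (Ka = 3e4 /M); if monovalent ions dominate
    (sqrt([Mg2+])/[Mon+] < 0.22) the monovalent-only quadratic in ln[Mon+]
    applies, otherwise the Mg2+ correction, with mixed-ion coefficients for
    0.22 <= ratio < 6.
    """
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    n_bp = len(seq)
    mg = mg_mM * 1e-3
    mon = mon_mM * 1e-3
    dntp = dntp_mM * 1e-3
    if dntp > 0 and mg > 0:
        ka = 3.0e4
        b = ka * dntp - ka * mg + 1.0
        mg = (-b + math.sqrt(b * b + 4.0 * ka * mg)) / (2.0 * ka)
    if mg <= 0:
        if mon <= 0:
            return 0.0
        lnm = math.log(mon)
        return (4.29 * fgc - 3.95) * 1e-5 * lnm + 9.40e-6 * lnm * lnm
    a, b, c, d = 3.92, -0.911, 6.26, 1.42
    e, f, g = -48.2, 52.5, 8.31
    if mon > 0:
        ratio = math.sqrt(mg) / mon
        if ratio < 0.22:
            lnm = math.log(mon)
            return (4.29 * fgc - 3.95) * 1e-5 * lnm + 9.40e-6 * lnm * lnm
        if ratio < 6.0:
            lnm = math.log(mon)
            a = 3.92 * (0.843 - 0.352 * math.sqrt(mon) * lnm)
            d = 1.42 * (1.279 - 4.03e-3 * lnm - 8.03e-3 * lnm * lnm)
            g = 8.31 * (0.486 - 0.258 * lnm + 5.25e-3 * lnm ** 3)
    lnmg = math.log(mg)
    return (
        a
        + b * lnmg
        + fgc * (c + d * lnmg)
        + (1.0 / (2.0 * (n_bp - 1))) * (e + f * lnmg + g * lnmg * lnmg)
    ) * 1e-5


def nn_tm(seq: str, params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Nearest-neighbour melting temperature of a primer (degC).

    The primer is given 5'->3' over {A,C,G,T}; its perfect complement is
    assumed as template, with primer in excess. Exactly symmetric under
    reverse complement (the duplex is the same molecule).
    """
    seq = seq.upper()
    # canonical duplex orientation: makes Tm(seq) == Tm(revcomp(seq)) bitwise
    # exact instead of merely equal up to float summation order
    seq = min(seq, revcomp(seq))
    if not 8 <= len(seq) <= 36:
        raise ValueError(f"primer length {len(seq)} outside supported 8-36 nt")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"ambiguity codes not allowed in Tm calculation: {sorted(bad)}"
        )
    dh, ds = INITIATION
    for i in range(len(seq) - 1):
        h, s = params.nn_table[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += TERMINAL_AT_PENALTY[0]
            ds += TERMINAL_AT_PENALTY[1]
    conc = params.primer_conc_nM * 1e-9
    if seq == revcomp(seq):
        ds += SYMMETRY_DS  # self-complementary: both strands identical
    tm_kelvin = (dh * 1000.0) / (ds + R_GAS * math.log(conc))
    corr = _owczarzy_inverse_tm_correction(
        seq, params.monovalent_mM, params.divalent_mM, params.dntp_mM
    )
    return 1.0 / (1.0 / tm_kelvin + corr) - 273.15
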