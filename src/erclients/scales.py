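"""Amino-acid propensity scales and membrane-insertion model constants.

Three scales are packaged here:

* Kyte & Doolittle hydropathy (J Mol Biol 157:105-132, 1982).
* Zimmerman polarity (Zimmerman, Eliezer & Simha, J Theor Biol 21:170-201,
  1968; AAindex entry ZIMJ680103).
* The "biological hydrophobicity" scale behind the apparent free energy of
  translocon-mediated transmembrane-helix insertion (Hessa et al., Nature
  450:1026-1030, 2007, supplementary material).  Each residue contributes a
  position-dependent free energy modelled as a Gaussian across the helix;
  Trp and Tyr carry two additional symmetric Gaussians describing their
  preference for the membrane interface.  The full model adds a
  hydrophobic-moment term and a quadratic helix-length correction.

All free energies are in kcal/mol.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Zimmerman polarity (dimensionless).
ZIMMERMAN_POLARITY = {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "Q": 3.53, "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
}

# Residue charges used for the N-region net charge: Lys/Arg +1, Asp/Glu -1,
# His and the chain termini contribute 0 (configurable at the call site).
RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

# Position-dependent insertion free-energy profiles (Hessa et al. 2007).
# For most residues the contribution at scaled position p in [-9, 9] is
#     dG(p) = a0 * exp(-a1 * p**2)
# Trp and Tyr carry two extra interface Gaussians:
#     dG(p) = a0 * exp(-a1 * p**2)
#             + a2 * (exp(-a3 * (p - a4)**2) + exp(-a3 * (p + a4)**2))
DG_PROFILES = {
    "A": (0.1267255, 0.0215152),
    "C": (-0.0765051, 0.0994228),
    "D": (1.7939795, 0.0172643),
    "E": (1.4193720, 0.0089351),
    "F": (-0.2766953, 0.0010297),
    "G": (0.4813492, 0.0047210),
    "H": (1.1998590, 0.0080127),
    "I": (-0.4597384, 0.0181495),
    "K": (1.8485768, 0.0218446),
    "L": (-0.4282992, 0.0023804),
    "M": (-0.0774786, 0.0984413),
    "N": (1.3266132, 0.0092375),
    "P": (1.0860888, 0.0100568),
    "Q": (1.3336109, 0.0111996),
    "R": (1.6492534, 0.0512044),
    "S": (0.7023921, 0.0077661),
    "T": (0.5266550, 0.0311973),
    "V": (-0.2447218, 0.0979201),
    "W": (0.2909390, 0.0189282, -0.5479140, 0.0930222, 6.4736619),
    "Y": (0.6275249, 0.0103896, -0.5744404, 0.0345763, 3.5614592),
}

# Hydrophobic-moment weight and helix-length correction
#     dG_total = sum_i dG_i + DG_C0 * mu + DG_C1 + DG_C2*L + DG_C3*L**2
# with mu the magnitude of the 100-degrees-per-residue moment of the dG_i.
DG_C0 = 0.27045
DG_C1 = 9.29274167549645
DG_C2 = -0.64513139783394
DG_C3 = 0.00822196628688

# Supported helix lengths for the fixed-span predictor.
DG_MIN_LENGTH = 9
DG_MAX_LENGTH = 40

# Standard genetic code (DNA codons) used for CDS handling.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

SENSE_CODONS = tuple(sorted(GENETIC_CODE))

CODONS_BY_RESIDUE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    CODONS_BY_RESIDUE.setdefault(_aa, tuple())
    CODONS_BY_RESIDUE[_aa] = CODONS_BY_RESIDUE[_aa] + (_codon,)
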