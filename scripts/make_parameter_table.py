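"""Generate src/hotforge/data/ff14sb_subset.csv.

Per-atom nonbonded parameters for the 20 canonical amino acids plus HID/HIP
histidine protonation variants, in the Amber ff94/ff14SB nonbonded convention
(charges in e, LJ given as sigma [A] / epsilon [kcal/mol] derived from the
Amber Rmin/2 values with sigma = Rmin * 2**(-1/6)).

Each atom row: res_name, atom_name, charge_e, sigma_A, epsilon_kcal_mol,
bonded_heavy_atom (set for hydrogens only).

The script asserts every residue's charges sum to its integer formal charge
within 1e-3 e before writing anything.
"""
import csv
import math
import pathlib

# LJ classes: Amber type -> (Rmin/2 A, epsilon kcal/mol)
LJ = {
    "N":  (1.8240, 0.1700),   # all nitrogens
    "CT": (1.9080, 0.1094),   # sp3 carbon
    "C":  (1.9080, 0.0860),   # sp2 carbon (carbonyl, aromatic, guanidinium)
    "O":  (1.6612, 0.2100),   # carbonyl / carboxylate oxygen
    "OH": (1.7210, 0.2104),   # hydroxyl oxygen
    "S":  (2.0000, 0.2500),   # sulfur (thiol and thioether)
    "H":  (0.6000, 0.0157),   # H on N
    "HO": (0.5000, 0.0000),   # H on O (Amber Rmin 0; small positive sigma, eps 0)
    "HS": (0.6000, 0.0157),   # H on S
    "HC": (1.4870, 0.0157),   # H on aliphatic C
    "H1": (1.3870, 0.0157),   # H on C bonded to one electronegative atom
    "HP": (1.1000, 0.0157),   # H on C bonded to positively charged N
    "HA": (1.4590, 0.0150),   # H on aromatic C
}


def sigma(rmin2):
    return 2.0 * rmin2 / (2.0 ** (1.0 / 6.0))


# Backbone shared by all residues except GLY and PRO.
# (atom, type, charge, parent-for-H)
def bb(n, h, ca, ha, c, o):
    return [
        ("N", "N", n, ""), ("H", "H", h, "N"),
        ("CA", "CT", ca, ""), ("HA", "H1", ha, "CA"),
        ("C", "C", c, ""), ("O", "O", o, ""),
    ]


BB0 = bb(-0.4157, 0.2719, None, None, 0.5973, -0.5679)  # neutral-residue frame


def res(name, formal, atoms):
    return (name, formal, atoms)


RESIDUES = [
    res("ALA", 0, bb(-0.4157, 0.2719, 0.0337, 0.0823, 0.5973, -0.5679) + [
        ("CB", "CT", -0.1825, ""),
        ("HB1", "HC", 0.0603, "CB"), ("HB2", "HC", 0.0603, "CB"), ("HB3", "HC", 0.0603, "CB"),
    ]),
    res("GLY", 0, [
        ("N", "N", -0.4157, ""), ("H", "H", 0.2719, "N"),
        ("CA", "CT", -0.0252, ""),
        ("HA2", "H1", 0.0698, "CA"), ("HA3", "H1", 0.0698, "CA"),
        ("C", "C", 0.5973, ""), ("O", "O", -0.5679, ""),
    ]),
    res("SER", 0, bb(-0.4157, 0.2719, -0.0249, 0.0843, 0.5973, -0.5679) + [
        ("CB", "CT", 0.2117, ""),
        ("HB2", "H1", 0.0352, "CB"), ("HB3", "H1", 0.0352, "CB"),
        ("OG", "OH", -0.6546, ""), ("HG", "HO", 0.4275, "OG"),
    ]),
    res("THR", 0, bb(-0.4157, 0.2719, -0.0389, 0.1007, 0.5973, -0.5679) + [
        ("CB", "CT", 0.3654, ""), ("HB", "H1", 0.0043, "CB"),
        ("CG2", "CT", -0.2438, ""),
        ("HG21", "HC", 0.0642, "CG2"), ("HG22", "HC", 0.0642, "CG2"), ("HG23", "HC", 0.0642, "CG2"),
        ("OG1", "OH", -0.6761, ""), ("HG1", "HO", 0.4102, "OG1"),
    ]),
    res("CYS", 0, bb(-0.4157, 0.2719, 0.0213, 0.1124, 0.5973, -0.5679) + [
        ("CB", "CT", -0.1231, ""),
        ("HB2", "H1", 0.1112, "CB"), ("HB3", "H1", 0.1112, "CB"),
        ("SG", "S", -0.3119, ""), ("HG", "HS", 0.1933, "SG"),
    ]),
    res("VAL", 0, bb(-0.4157, 0.2719, -0.0875, 0.0969, 0.5973, -0.5679) + [
        ("CB", "CT", 0.2985, ""), ("HB", "HC", -0.0297, "CB"),
        ("CG1", "CT", -0.3192, ""),
        ("HG11", "HC", 0.0791, "CG1"), ("HG12", "HC", 0.0791, "CG1"), ("HG13", "HC", 0.0791, "CG1"),
        ("CG2", "CT", -0.3192, ""),
        ("HG21", "HC", 0.0791, "CG2"), ("HG22", "HC", 0.0791, "CG2"), ("HG23", "HC", 0.0791, "CG2"),
    ]),
    res("LEU", 0, bb(-0.4157, 0.2719, -0.0518, 0.0922, 0.5973, -0.5679) + [
        ("CB", "CT", -0.1102, ""),
        ("HB2", "HC", 0.0457, "CB"), ("HB3", "HC", 0.0457, "CB"),
        ("CG", "CT", 0.3531, ""), ("HG", "HC", -0.0361, "CG"),
        ("CD1", "CT", -0.4121, ""),
        ("HD11", "HC", 0.1000, "CD1"), ("HD12", "HC", 0.1000, "CD1"), ("HD13", "HC", 0.1000, "CD1"),
        ("CD2", "CT", -0.4121, ""),
        ("HD21", "HC", 0.1000, "CD2"), ("HD22", "HC", 0.1000, "CD2"), ("HD23", "HC", 0.1000, "CD2"),
    ]),
    res("ILE", 0, bb(-0.4157, 0.2719, -0.0597, 0.0869, 0.5973, -0.5679) + [
        ("CB", "CT", 0.1303, ""), ("HB", "HC", 0.0187, "CB"),
        ("CG2", "CT", -0.3204, ""),
        ("HG21", "HC", 0.0882, "CG2"), ("HG22", "HC", 0.0882, "CG2"), ("HG23", "HC", 0.0882, "CG2"),
        ("CG1", "CT", -0.0430, ""),
        ("HG12", "HC", 0.0236, "CG1"), ("HG13", "HC", 0.0236, "CG1"),
        ("CD1", "CT", -0.0660, ""),
        ("HD11", "HC", 0.0186, "CD1"), ("HD12", "HC", 0.0186, "CD1"), ("HD13", "HC", 0.0186, "CD1"),
    ]),
    res("PRO", 0, [
        ("N", "N", -0.2548, ""),
        ("CD", "CT", 0.0192, ""),
        ("HD2", "H1", 0.0391, "CD"), ("HD3", "H1", 0.0391, "CD"),
        ("CG", "CT", 0.0189, ""),
        ("HG2", "HC", 0.0213, "CG"), ("HG3", "HC", 0.0213, "CG"),
        ("CB", "CT", -0.0070, ""),
        ("HB2", "HC", 0.0253, "CB"), ("HB3", "HC", 0.0253, "CB"),
        ("CA", "CT", -0.0266, ""), ("HA", "H1", 0.0641, "CA"),
        ("C", "C", 0.5896, ""), ("O", "O", -0.5748, ""),
    ]),
    res("PHE", 0, bb(-0.4157, 0.2719, -0.0024, 0.0978, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0343, ""),
        ("HB2", "HC", 0.0295, "CB"), ("HB3", "HC", 0.0295, "CB"),
        ("CG", "C", 0.0118, ""),
        ("CD1", "C", -0.1256, ""), ("HD1", "HA", 0.1330, "CD1"),
        ("CE1", "C", -0.1704, ""), ("HE1", "HA", 0.1430, "CE1"),
        ("CZ", "C", -0.1072, ""), ("HZ", "HA", 0.1297, "CZ"),
        ("CE2", "C", -0.1704, ""), ("HE2", "HA", 0.1430, "CE2"),
        ("CD2", "C", -0.1256, ""), ("HD2", "HA", 0.1330, "CD2"),
    ]),
    res("TYR", 0, bb(-0.4157, 0.2719, -0.0014, 0.0876, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0152, ""),
        ("HB2", "HC", 0.0295, "CB"), ("HB3", "HC", 0.0295, "CB"),
        ("CG", "C", -0.0011, ""),
        ("CD1", "C", -0.1906, ""), ("HD1", "HA", 0.1699, "CD1"),
        ("CE1", "C", -0.2341, ""), ("HE1", "HA", 0.1656, "CE1"),
        ("CZ", "C", 0.3226, ""),
        ("OH", "OH", -0.5579, ""), ("HH", "HO", 0.3992, "OH"),
        ("CE2", "C", -0.2341, ""), ("HE2", "HA", 0.1656, "CE2"),
        ("CD2", "C", -0.1906, ""), ("HD2", "HA", 0.1699, "CD2"),
    ]),
    res("TRP", 0, bb(-0.4157, 0.2719, -0.0275, 0.1123, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0050, ""),
        ("HB2", "HC", 0.0339, "CB"), ("HB3", "HC", 0.0339, "CB"),
        ("CG", "C", -0.1415, ""),
        ("CD1", "C", -0.1638, ""), ("HD1", "HA", 0.2062, "CD1"),
        ("NE1", "N", -0.3418, ""), ("HE1", "H", 0.3412, "NE1"),
        ("CE2", "C", 0.1380, ""),
        ("CZ2", "C", -0.2601, ""), ("HZ2", "HA", 0.1572, "CZ2"),
        ("CH2", "C", -0.1134, ""), ("HH2", "HA", 0.1417, "CH2"),
        ("CZ3", "C", -0.1972, ""), ("HZ3", "HA", 0.1447, "CZ3"),
        ("CE3", "C", -0.2387, ""), ("HE3", "HA", 0.1700, "CE3"),
        ("CD2", "C", 0.1243, ""),
    ]),
    res("ASP", -1, bb(-0.5163, 0.2936, 0.0381, 0.0880, 0.5366, -0.5819) + [
        ("CB", "CT", -0.0303, ""),
        ("HB2", "HC", -0.0122, "CB"), ("HB3", "HC", -0.0122, "CB"),
        ("CG", "C", 0.7994, ""),
        ("OD1", "O", -0.8014, ""), ("OD2", "O", -0.8014, ""),
    ]),
    res("GLU", -1, bb(-0.5163, 0.2936, 0.0397, 0.1105, 0.5366, -0.5819) + [
        ("CB", "CT", 0.0560, ""),
        ("HB2", "HC", -0.0173, "CB"), ("HB3", "HC", -0.0173, "CB"),
        ("CG", "CT", 0.0136, ""),
        ("HG2", "HC", -0.0425, "CG"), ("HG3", "HC", -0.0425, "CG"),
        ("CD", "C", 0.8054, ""),
        ("OE1", "O", -0.8188, ""), ("OE2", "O", -0.8188, ""),
    ]),
    res("ASN", 0, bb(-0.4157, 0.2719, 0.0143, 0.1048, 0.5973, -0.5679) + [
        ("CB", "CT", -0.2041, ""),
        ("HB2", "HC", 0.0797, "CB"), ("HB3", "HC", 0.0797, "CB"),
        ("CG", "C", 0.7130, ""),
        ("OD1", "O", -0.5931, ""),
        ("ND2", "N", -0.9191, ""),
        ("HD21", "H", 0.4196, "ND2"), ("HD22", "H", 0.4196, "ND2"),
    ]),
    res("GLN", 0, bb(-0.4157, 0.2719, -0.0031, 0.0850, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0036, ""),
        ("HB2", "HC", 0.0171, "CB"), ("HB3", "HC", 0.0171, "CB"),
        ("CG", "CT", -0.0645, ""),
        ("HG2", "HC", 0.0352, "CG"), ("HG3", "HC", 0.0352, "CG"),
        ("CD", "C", 0.6951, ""),
        ("OE1", "O", -0.6086, ""),
        ("NE2", "N", -0.9407, ""),
        ("HE21", "H", 0.4251, "NE2"), ("HE22", "H", 0.4251, "NE2"),
    ]),
    res("LYS", 1, bb(-0.3479, 0.2747, -0.2400, 0.1426, 0.7341, -0.5894) + [
        ("CB", "CT", -0.0094, ""),
        ("HB2", "HC", 0.0362, "CB"), ("HB3", "HC", 0.0362, "CB"),
        ("CG", "CT", 0.0187, ""),
        ("HG2", "HC", 0.0103, "CG"), ("HG3", "HC", 0.0103, "CG"),
        ("CD", "CT", -0.0479, ""),
        ("HD2", "HC", 0.0621, "CD"), ("HD3", "HC", 0.0621, "CD"),
        ("CE", "CT", -0.0143, ""),
        ("HE2", "HP", 0.1135, "CE"), ("HE3", "HP", 0.1135, "CE"),
        ("NZ", "N", -0.3854, ""),
        ("HZ1", "H", 0.3400, "NZ"), ("HZ2", "H", 0.3400, "NZ"), ("HZ3", "H", 0.3400, "NZ"),
    ]),
    res("ARG", 1, bb(-0.3479, 0.2747, -0.2637, 0.1560, 0.7341, -0.5894) + [
        ("CB", "CT", -0.0007, ""),
        ("HB2", "HC", 0.0327, "CB"), ("HB3", "HC", 0.0327, "CB"),
        ("CG", "CT", 0.0390, ""),
        ("HG2", "HC", 0.0285, "CG"), ("HG3", "HC", 0.0285, "CG"),
        ("CD", "CT", 0.0486, ""),
        ("HD2", "H1", 0.0687, "CD"), ("HD3", "H1", 0.0687, "CD"),
        ("NE", "N", -0.5295, ""), ("HE", "H", 0.3456, "NE"),
        ("CZ", "C", 0.8076, ""),
        ("NH1", "N", -0.8627, ""),
        ("HH11", "H", 0.4478, "NH1"), ("HH12", "H", 0.4478, "NH1"),
        ("NH2", "N", -0.8627, ""),
        ("HH21", "H", 0.4478, "NH2"), ("HH22", "H", 0.4478, "NH2"),
    ]),
    res("MET", 0, bb(-0.4157, 0.2719, -0.0237, 0.0880, 0.5973, -0.5679) + [
        ("CB", "CT", 0.0342, ""),
        ("HB2", "HC", 0.0241, "CB"), ("HB3", "HC", 0.0241, "CB"),
        ("CG", "CT", 0.0018, ""),
        ("HG2", "H1", 0.0440, "CG"), ("HG3", "H1", 0.0440, "CG"),
        ("SD", "S", -0.2737, ""),
        ("CE", "CT", -0.0536, ""),
        ("HE1", "H1", 0.0684, "CE"), ("HE2", "H1", 0.0684, "CE"), ("HE3", "H1", 0.0684, "CE"),
    ]),
    # Histidine: HIE (Nepsilon-protonated) is the package default for "HIS".
    res("HIE", 0, bb(-0.4157, 0.2719, -0.0581, 0.1360, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0074, ""),
        ("HB2", "HC", 0.0367, "CB"), ("HB3", "HC", 0.0367, "CB"),
        ("CG", "C", 0.1868, ""),
        ("ND1", "N", -0.5432, ""),
        ("CE1", "C", 0.1635, ""), ("HE1", "HA", 0.1435, "CE1"),
        ("NE2", "N", -0.2795, ""), ("HE2", "H", 0.3339, "NE2"),
        ("CD2", "C", -0.2207, ""), ("HD2", "HA", 0.1862, "CD2"),
    ]),
    res("HID", 0, bb(-0.4157, 0.2719, 0.0188, 0.0881, 0.5973, -0.5679) + [
        ("CB", "CT", -0.0462, ""),
        ("HB2", "HC", 0.0402, "CB"), ("HB3", "HC", 0.0402, "CB"),
        ("CG", "C", -0.0266, ""),
        ("ND1", "N", -0.3811, ""), ("HD1", "H", 0.3649, "ND1"),
        ("CE1", "C", 0.2057, ""), ("HE1", "HA", 0.1392, "CE1"),
        ("NE2", "N", -0.5727, ""),
        ("CD2", "C", 0.1292, ""), ("HD2", "HA", 0.1147, "CD2"),
    ]),
    res("HIP", 1, bb(-0.3479, 0.2747, -0.1354, 0.1212, 0.7341, -0.5894) + [
        ("CB", "CT", -0.0414, ""),
        ("HB2", "HC", 0.0810, "CB"), ("HB3", "HC", 0.0810, "CB"),
        ("CG", "C", -0.0012, ""),
        ("ND1", "N", -0.1513, ""), ("HD1", "H", 0.3866, "ND1"),
        ("CE1", "C", -0.0170, ""), ("HE1", "HA", 0.2681, "CE1"),
        ("NE2", "N", -0.1718, ""), ("HE2", "H", 0.3911, "NE2"),
        ("CD2", "C", -0.1141, ""), ("HD2", "HA", 0.2317, "CD2"),
    ]),
]


def main():
    out = pathlib.Path(__file__).resolve().parents[1] / "src/hotforge/data/ff14sb_subset.csv"
    rows = []
    for name, formal, atoms in RESIDUES:
        total = sum(q for _, _, q, _ in atoms)
        if abs(total - formal) > 1e-3:
            raise SystemExit(f"{name}: charge sum {total:.4f} != formal {formal}")
        seen = set()
        for aname, atype, q, parent in atoms:
            assert aname not in seen, (name, aname)
            seen.add(aname)
            if aname.startswith("H"):
                assert parent and parent in {a for a, _, _, _ in atoms}, (name, aname)
            rmin2, eps = LJ[atype]
            rows.append((name, aname, f"{q:.4f}", f"{sigma(rmin2):.6f}", f"{eps:.4f}", parent))
    with out.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["res_name", "atom_name", "charge_e", "sigma_A", "epsilon_kcal_mol", "bonded_heavy_atom"])
        w.writerows(rows)
    print(f"wrote {out} ({len(rows)} atoms, {len(RESIDUES)} residues)")


if __name__ == "__main__":
    main()
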