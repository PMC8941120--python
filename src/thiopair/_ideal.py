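"""Ideal stereochemistry constants shared by the geometry and fixture modules.

All lengths in Angstrom, all angles in degrees. The values are standard
amino-acid stereochemistry (Engh–Huber-like); every generated fixture and every
reconstructed side chain uses this one table so that geometric assertions have
closed-form expectations.
"""

# backbone
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
N_CA_C = 111.2
CA_C_N = 116.2
C_N_CA = 121.7
CA_C_O = 120.8
OMEGA = 180.0

# cysteine / penicillamine side chain
CA_CB = 1.53
CB_SG = 1.81
N_CA_CB = 110.5
CA_CB_SG = 114.4
CB_CG = 1.53            # Pen beta-methyls
TETRAHEDRAL = 109.47

# disulfide bridge
SS_BOND = 2.04
CB_S_S = 104.2
CHI3_CANONICAL = 87.0   # |CB-SG-SG'-CB'| at the canonical bridge geometry
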