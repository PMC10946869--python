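"""Physical constants and instrument defaults.

The proton mass used throughout is the adducted-proton convention common in
native protein mass spectrometry (average-mass regime, consistent with
one-decimal m/z reporting at low resolving power). It can be overridden per
call wherever it enters an equation.
"""

#: Mass of the adducted proton, Da.
PROTON_MASS: float = 1.00728

#: Adduct masses for singly charged small-molecule ions, Da.
ADDUCT_MASSES: dict[str, float] = {
    "H": 1.00728,
    "Na": 22.98922,
    "K": 38.96316,
}

#: Upper m/z isolation ceiling of a quadrupole in multiplexed mode, Th.
QUADRUPOLE_ISOLATION_CEILING: float = 2000.0

#: Upper m/z isolation ceiling of a linear ion trap (single precursor), Th.
ION_TRAP_ISOLATION_CEILING: float = 8000.0

#: Default charge search ceiling for deconvolution; covers native proteins
#: to ~1 MDa at m/z < 20,000.
DEFAULT_MAX_CHARGE: int = 50

#: Default sanity bound on the mass spread of an accepted charge assignment, Da.
DEFAULT_SPREAD_BOUND: float = 5.0

#: Default centroid matching tolerance, Th.
DEFAULT_MATCH_TOLERANCE: float = 0.5
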