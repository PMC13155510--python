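"""Cell-kind codes shared across the lattice, agent and engine modules.

The tumor microenvironment (TME) is a 2D lattice in which every site holds at
most one agent.  Vessels are immobile non-agent sites used for macrophage
recruitment and drug influx.
"""

EMPTY = 0
TC_ACTIVE = 1      # actively cycling tumor cell (has proliferative space)
TC_QUIESCENT = 2   # tumor cell with fully occupied Moore neighborhood; age frozen
M0 = 3             # undifferentiated recruited macrophage
M1 = 4             # antitumorigenic (phagocytic) macrophage
M2 = 5             # protumorigenic macrophage
DC = 6             # dead cell awaiting clearance
VESSEL = 7         # vascular site (immobile, not an agent)

KIND_NAMES = {
    EMPTY: "empty",
    TC_ACTIVE: "TC_active",
    TC_QUIESCENT: "TC_quiescent",
    M0: "M0",
    M1: "M1",
    M2: "M2",
    DC: "DC",
    VESSEL: "vessel",
}

TC_KINDS = (TC_ACTIVE, TC_QUIESCENT)
TAM_KINDS = (M0, M1, M2)

FIELD_NAMES = ("CSF1", "EGF", "IGF1", "CSF1R_I", "IGF1R_I")
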