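"""Seven-way subpopulation taxonomy for triple-labelled sEVPs.

Particles carry up to three fluorescent markers: COE (a water-soluble
membrane dye staining the lipid bilayer), CFSE (a luminal esterase/cargo
marker) and CD63 (a tetraspanin surface protein labelled with PE-Cy5
antibodies).  COE positivity splits the population into vesicular sEVs
(COE+) and non-vesicular nanoparticles, NPs (COE-); the CFSE and CD63
booleans select the sub-label.  The all-negative combination is not a
particle, leaving exactly seven admissible classes.
"""

from __future__ import annotations

COE = "COE"
CFSE = "CFSE"
CD63 = "CD63"

#: Canonical channel order used throughout the package.
CHANNELS: tuple[str, ...] = (COE, CFSE, CD63)

#: The seven subpopulation labels, vesicular (sEV) classes first.
SUBPOPULATION_LABELS: tuple[str, ...] = (
    "sEV CFSE+CD63+",
    "sEV CFSE+CD63-",
    "sEV CFSE-CD63+",
    "sEV CFSE-CD63-",
    "NP CFSE+CD63+",
    "NP CFSE+CD63-",
    "NP CFSE-CD63+",
)

#: label -> (COE+, CFSE+, CD63+)
POSITIVITY_OF_LABEL: dict[str, tuple[bool, bool, bool]] = {
    "sEV CFSE+CD63+": (True, True, True),
    "sEV CFSE+CD63-": (True, True, False),
    "sEV CFSE-CD63+": (True, False, True),
    "sEV CFSE-CD63-": (True, False, False),
    "NP CFSE+CD63+": (False, True, True),
    "NP CFSE+CD63-": (False, True, False),
    "NP CFSE-CD63+": (False, False, True),
}

_LABEL_OF_POSITIVITY = {v: k for k, v in POSITIVITY_OF_LABEL.items()}

SEV_LABELS: tuple[str, ...] = tuple(l for l in SUBPOPULATION_LABELS if l.startswith("sEV"))
NP_LABELS: tuple[str, ...] = tuple(l for l in SUBPOPULATION_LABELS if l.startswith("NP"))


def categorize(coe_positive: bool, cfse_positive: bool, cd63_positive: bool) -> str:
    """Map per-channel positivity to one of the seven subpopulation labels.

    Deterministic total function on the seven admissible boolean triples.
    Raises ``ValueError`` on the all-negative triple, which violates the
    particle contract (a detected particle is positive in at least one
    channel).
    """
    key = (bool(coe_positive), bool(cfse_positive), bool(cd63_positive))
    if key == (False, False, False):
        raise ValueError("all-negative particle: at least one channel must be positive")
    return _LABEL_OF_POSITIVITY[key]
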