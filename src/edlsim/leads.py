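"""Standard 12-lead ECG derivation from the 64-lead body-surface setup.

Limb-equivalent electrodes (RA, LA, LL) and the precordial positions
V1..V6 are labelled members of the 64-electrode grid.  Einthoven limb
leads, Goldberger augmented leads and Wilson precordial leads follow the
textbook definitions; the Wilson central terminal is the mean of RA, LA
and LL.
"""

from __future__ import annotations

import numpy as np

from .anatomy import AnatomyModel, ConfigurationError, REQUIRED_LEADS
from .sources import PotentialTraces

__all__ = ["derive_12lead", "LEAD_NAMES"]

LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]


def derive_12lead(bsp64: PotentialTraces, anatomy: AnatomyModel) -> PotentialTraces:
    """Standard 12-lead ECG from the 64-lead body-surface potentials."""
    missing = REQUIRED_LEADS - set(anatomy.lead_map)
    if missing:
        raise ConfigurationError(f"lead map missing {sorted(missing)}")
    el = {name: bsp64.values[idx] for name, idx in anatomy.lead_map.items()}
    ra, la, ll = el["RA"], el["LA"], el["LL"]
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
        leads[v] = el[v] - wct
    return PotentialTraces(
        bsp64.times,
        np.vstack([leads[name] for name in LEAD_NAMES]),
        labels=list(LEAD_NAMES),
        metadata=dict(bsp64.metadata, derived="12lead"),
    )
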