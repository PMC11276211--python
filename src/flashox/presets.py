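"""Reference parameter sets for PSII-enriched (BBY) membrane preparations.

Three preparations are covered: intact PSII BBY membranes ("control"),
membranes salt-washed to remove the extrinsic proteins PsbP and PsbQ
("pq"), and membranes stripped of PsbO, PsbP and PsbQ ("opq").  The
five-state rows describe the flash-pattern analysis (misses ``alpha_i``,
fast-release fraction ``d``, acceptor-pool damping ``C``, initial S-state
distribution); the relaxation rows describe the biphasic Y3(dt) kinetics
(amplitudes and time constants of the fast and slow O2-release phases).

These sets serve as generating truths for the package's self-consistency
recovery suites and as realistic defaults for the synthetic-data module.
"""

from __future__ import annotations

from .kinetics import BiexpParams
from .sstate import FiveSParams

__all__ = ["FIVE_S_ROWS", "BIEXP_ROWS", "ROW_NAMES"]

ROW_NAMES = ("control", "pq", "opq")

FIVE_S_ROWS: dict[str, FiveSParams] = {
    # intact PSII BBY
    "control": FiveSParams(
        alpha=(0.001, 0.001, 0.785, 0.001),
        d=0.85,
        C=0.995,
        init=(0.05, 0.87, 0.08, 0.00),
    ),
    # PsbP + PsbQ removed (1.5 M NaCl wash)
    "pq": FiveSParams(
        alpha=(0.55, 0.28, 0.78, 0.12),
        d=0.30,
        C=0.967,
        init=(0.04, 0.88, 0.08, 0.00),
    ),
    # PsbO + PsbP + PsbQ removed (1.5 M MgCl2 wash)
    "opq": FiveSParams(
        alpha=(0.51, 0.27, 0.79, 0.16),
        d=0.02,
        C=0.990,
        init=(0.282, 0.530, 0.130, 0.058),
    ),
}

BIEXP_ROWS: dict[str, BiexpParams] = {
    "control": BiexpParams(a_fast=0.73, tau_fast=4.1, a_slow=0.27, tau_slow=44.2),
    "pq": BiexpParams(a_fast=0.26, tau_fast=6.2, a_slow=0.74, tau_slow=22.2),
    # single slow component: the fast release channel is shut down
    "opq": BiexpParams(a_fast=0.0, tau_fast=None, a_slow=1.00, tau_slow=13.0),
}
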