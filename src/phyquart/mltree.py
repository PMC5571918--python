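"""Plain ML quartet-topology selection — the baseline the polarized
site-pattern score is compared against.

All three topologies are fitted with the shared likelihood core and the one
with the highest optimized log-likelihood wins.  The baseline protocol fixes
the ASRV parameters (gamma shape and invariant proportion) to the values
used in simulation while relative rates and base composition are estimated
from the data, mirroring a best-case ML analysis whose only misspecification
is the discrete-gamma approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

from phyquart.errors import InputError
from phyquart.patterns import TOPOLOGIES, PatternTally
from phyquart.scoring import fit_all_topologies

#: logL differences below this are a tie (scored as a failure: a tie does
#: not identify the correct tree)
TIE_TOLERANCE = 1e-6


@dataclass
class MLResult:
    logL: dict
    winner: str
    fits: dict


def ml_quartet(
    t: PatternTally,
    mode: str = "fixed_alpha_inv",
    *,
    fixed_alpha: float | None = None,
    fixed_p_inv: float | None = None,
    n_cat: int = 4,
    tol: float = 1e-6,
) -> MLResult:
    """Fit all three topologies and pick the ML winner ('tie' if the best two
    log-likelihoods differ by less than :data:`TIE_TOLERANCE`)."""
    if t.L == 0:
        raise InputError("empty tally")
    fits = fit_all_topologies(t, mode, fixed_alpha=fixed_alpha,
                              fixed_p_inv=fixed_p_inv, n_cat=n_cat, tol=tol)
    logL = {topo: fits[topo].logL for topo in TOPOLOGIES}
    ranked = sorted(TOPOLOGIES, key=lambda x: logL[x], reverse=True)
    if logL[ranked[0]] - logL[ranked[1]] < TIE_TOLERANCE:
        winner = "tie"
    else:
        winner = ranked[0]
    return MLResult(logL=logL, winner=winner, fits=fits)
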