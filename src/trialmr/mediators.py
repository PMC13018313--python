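"""Direction-consistency classification of candidate mediating biomarkers.

A signature biomarker is a *candidate mediator* for an outcome when its
relationship to the signature and to disease risk line up with the
signature's overall protective association: biomarkers the intervention
raises (positive weight) should associate with lower risk, and biomarkers
it lowers (negative weight) with higher risk.  The observational
association must survive FDR (q < 0.05) and the MR estimate must agree in
direction (no MR significance gate: direction agreement alone is required,
so imprecise but concordant MR evidence still supports candidacy).
Significant associations with the *reverse* pairing are off-target
signals; everything else is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = ("candidate_mediator", "off_target", "not_significant")


@dataclass(frozen=True)
class MediatorEvidence:
    """Evidence row for one biomarker against one outcome.

    ``weight_sign`` is the sign (+1/-1) of the biomarker's signature
    weight; ``obs_logor``/``obs_q`` come from the covariate-adjusted
    logistic association of the outcome with the biomarker; ``mr_beta`` is
    the MR estimate (``None`` when no instruments were found).
    """

    biomarker: str
    weight_sign: int
    obs_logor: float
    obs_q: float
    mr_beta: float | None = None
    cis_beta: float | None = None

    def __post_init__(self):
        if self.weight_sign not in (-1, 1):
            raise ValueError("weight_sign must be +1 or -1")


@dataclass(frozen=True)
class MediatorCall:
    biomarker: str
    outcome: str
    category: str
    rationale: str


def classify_biomarker(ev: MediatorEvidence, outcome: str = "",
                       alpha: float = 0.05) -> MediatorCall:
    """Apply the three direction-consistency rules to one evidence row.

    candidate_mediator: (weight<0 and obs log-OR>0) or (weight>0 and
    obs log-OR<0), with obs q < alpha and sign(MR) == sign(obs).
    off_target: obs q < alpha but the pairing is reversed (the biomarker
    moves with the signature yet with *higher* risk, or against it with
    lower risk).  Everything else: not_significant.  A missing MR estimate
    classifies on the observational rules alone, flagged in the rationale.
    """
    s_w, b_obs = ev.weight_sign, ev.obs_logor
    protective_pairing = (s_w < 0 and b_obs > 0) or (s_w > 0 and b_obs < 0)
    if ev.obs_q >= alpha or b_obs == 0:
        cat = "not_significant"
        why = f"observational q={ev.obs_q:.3g} >= {alpha}"
    elif protective_pairing:
        if ev.mr_beta is None:
            cat = "candidate_mediator"
            why = ("consistent pairing, obs q<%g; no MR estimate available "
                   "(classified on observational rules)" % alpha)
        elif (ev.mr_beta > 0) == (b_obs > 0):
            cat = "candidate_mediator"
            why = "consistent pairing, obs q<%g, MR direction agrees" % alpha
        else:
            cat = "not_significant"
            why = "MR direction disagrees with the observational association"
    else:
        cat = "off_target"
        why = ("significant but reversed pairing: the biomarker moves %s the "
               "signature yet associates with %s risk"
               % ("with" if s_w > 0 else "against",
                  "higher" if b_obs > 0 else "lower"))
    return MediatorCall(ev.biomarker, outcome, cat, why)


def select_mediators(panel: list[MediatorEvidence], outcome: str,
                     alpha: float = 0.05) -> list[MediatorCall]:
    """Classify every biomarker; candidates ordered by observational q."""
    names = [ev.biomarker for ev in panel]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate biomarker rows: {dupes}")
    calls = [classify_biomarker(ev, outcome, alpha) for ev in panel]
    qs = {ev.biomarker: ev.obs_q for ev in panel}
    cand = sorted([c for c in calls if c.category == "candidate_mediator"],
                  key=lambda c: qs[c.biomarker])
    rest = [c for c in calls if c.category != "candidate_mediator"]
    return cand + rest


def calls_frame(calls: list[MediatorCall]) -> pd.DataFrame:
    return pd.DataFrame([{"biomarker": c.biomarker, "outcome": c.outcome,
                          "category": c.category, "rationale": c.rationale}
                         for c in calls])
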