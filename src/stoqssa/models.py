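"""Case-study reaction networks, in full (elementary) and reduced form.

Three small systems, each built around one rapid reversible binding pair,
exercise the reduction machinery in the regimes where the stQSSA fails
and the slQSSA rescues it:

* a gene regulatory network: DNA D and a transcription factor P bind
  rapidly; unbound D drives a repressed transcript M_R, the complex D:P
  drives an activated transcript M_A;
* a transcriptional negative-feedback oscillator (circadian-clock style):
  activator A drives transcription of M, whose protein product matures
  through three steps into repressor R, which sequesters A;
* a bistable mitotic switch: inactive cyclin B/Cdc2 (P) is activated to
  M through a positive feedback, while Suc1 (B) sequesters M; total
  active M_T switches between a lower and an upper mode separated by
  M_T = B_T.

The published values fixed here are the dissociation constants and
totals of each regime and the elementary binding rates of the isolated
motif (k_f/Omega = 1e4 s^-1, k_b = 1 s^-1).  The remaining slow rate
constants are package defaults chosen to reproduce each system's
qualitative regime (tight-binding distortion vs. accurate weak-binding
reduction) at desk-scale simulation cost; they are flagged with
``placeholder_rates=True`` in the model metadata.
"""

from __future__ import annotations

from stoqssa.ssa import QssaTerm, Reaction, ReactionNetwork

__all__ = [
    "make_binding_motif",
    "make_gene_network",
    "make_oscillator",
    "make_bistable_switch",
    "GENE_DEFAULTS",
    "OSCILLATOR_DEFAULTS",
    "BISTABLE_DEFAULTS",
]

#: default unbinding rate for the case-study pairs; together with each
#: model's K_d this fixes k_f/Omega = kb / K_d and keeps the binding
#: channel two orders faster than the slow reactions.
DEFAULT_KB = 50.0

GENE_DEFAULTS = dict(alpha_r=1.0, alpha_a=1.0, delta=1.0, kb=25.0)
OSCILLATOR_DEFAULTS = dict(
    alpha_m=100.0, delta_m=1.0, alpha_p=0.05, beta=1.0, delta_r=3.0,
    delta_c=0.02, kb=400.0,
)
BISTABLE_DEFAULTS = dict(k0=0.24, k1=1.0, delta=2.0, C_T=20, kb=DEFAULT_KB)


def _meta(variant: str, estimator: str | None, **params) -> dict:
    meta = {"variant": variant, "placeholder_rates": True, **params}
    if estimator is not None:
        meta["estimator"] = estimator
    return meta


def make_binding_motif(
    A_T: int, B_T: int, kf_over_omega: float, kb: float
) -> ReactionNetwork:
    """The isolated reversible binding pair A + B <-> C (full model only)."""
    if kf_over_omega <= 0 or kb <= 0:
        raise ValueError("rates must be positive")
    net = ReactionNetwork(
        species=["A", "B", "C"],
        initial={"A": A_T, "B": B_T, "C": 0},
        reactions=[
            Reaction(
                "bind", {"A": -1, "B": -1, "C": +1}, kf_over_omega,
                reactants={"A": 1, "B": 1},
            ),
            Reaction("unbind", {"A": +1, "B": +1, "C": -1}, kb, reactants={"C": 1}),
        ],
        conserved_totals=[
            ("A_T", {"A": 1, "C": 1}, A_T),
            ("B_T", {"B": 1, "C": 1}, B_T),
        ],
        name="binding_motif",
        metadata={
            "variant": "full",
            "placeholder_rates": False,
            "K_d": kb / kf_over_omega,
        },
    )
    return net


def make_gene_network(
    variant: str,
    D_T: int = 10,
    P_T: int = 10,
    K_d: float = 1e-2,
    estimator: str = "stqssa",
    **slow_rates,
) -> ReactionNetwork:
    """Gene regulatory network with repressed (M_R) and activated (M_A) genes.

    Full variant: species D, P, D:P, M_R, M_A with elementary binding;
    M_R transcription is proportional to unbound D, M_A transcription to
    the complex.  Reduced variant: M_R and M_A only, with transcription
    propensities using a QSSA estimator of D and D:P evaluated at the
    conserved totals (D_T, P_T).
    """
    p = {**GENE_DEFAULTS, **slow_rates}
    ar, aa, de, kb = p["alpha_r"], p["alpha_a"], p["delta"], p["kb"]
    if variant == "full":
        kf = kb / K_d
        return ReactionNetwork(
            species=["D", "P", "DP", "M_R", "M_A"],
            initial={"D": D_T, "P": P_T, "DP": 0, "M_R": 0, "M_A": 0},
            reactions=[
                Reaction("bind", {"D": -1, "P": -1, "DP": +1}, kf,
                         reactants={"D": 1, "P": 1}),
                Reaction("unbind", {"D": +1, "P": +1, "DP": -1}, kb,
                         reactants={"DP": 1}),
                Reaction("transcribe_R", {"M_R": +1}, ar, modifiers={"D": 1}),
                Reaction("transcribe_A", {"M_A": +1}, aa, modifiers={"DP": 1}),
                Reaction("decay_R", {"M_R": -1}, de, reactants={"M_R": 1}),
                Reaction("decay_A", {"M_A": -1}, de, reactants={"M_A": 1}),
            ],
            conserved_totals=[
                ("D_T", {"D": 1, "DP": 1}, D_T),
                ("P_T", {"P": 1, "DP": 1}, P_T),
            ],
            name="gene_network_full",
            metadata=_meta("full", None, D_T=D_T, P_T=P_T, K_d=K_d, **p),
        )
    if variant == "reduced":
        pair = dict(total=float(D_T), partner=float(P_T), K_d=K_d,
                    pair_name="DP")
        return ReactionNetwork(
            species=["M_R", "M_A"],
            initial={"M_R": 0, "M_A": 0},
            reactions=[
                Reaction("transcribe_R", {"M_R": +1}, ar,
                         qssa=QssaTerm(role="unbound", estimator=estimator, **pair)),
                Reaction("transcribe_A", {"M_A": +1}, aa,
                         qssa=QssaTerm(role="complex", estimator=estimator, **pair)),
                Reaction("decay_R", {"M_R": -1}, de, reactants={"M_R": 1}),
                Reaction("decay_A", {"M_A": -1}, de, reactants={"M_A": 1}),
            ],
            name="gene_network_reduced",
            metadata=_meta("reduced", estimator, D_T=D_T, P_T=P_T, K_d=K_d, **p),
        )
    raise ValueError(f"variant must be full|reduced, got {variant!r}")


def make_oscillator(
    variant: str,
    A_T: int = 5,
    K_d: float = 1e-4,
    estimator: str = "stqssa",
    **slow_rates,
) -> ReactionNetwork:
    """Transcriptional negative-feedback oscillator with sequestration.

    Activator A transcribes M (rate alpha_m per free A); M translates
    into P_1 which matures P_1 -> P_2 -> P_3 -> R; repressor R binds A
    rapidly.  Degradation removes free R at delta_r and the complex A:R
    at the much smaller delta_c (releasing A), so once R_T falls to ~A_T
    nearly all remaining R is sequestered and R_T lingers near the 1:1
    point -- the regime where the stQSSA's overestimate of free A
    distorts the clock.  The reduced variant keeps the slow species
    (R_T, M, P_1..P_3); the transcription propensity uses a QSSA estimate
    of free A and the two degradation channels use the matching free-R
    and complex estimates, all at the current (A_T, R_T).
    """
    p = {**OSCILLATOR_DEFAULTS, **slow_rates}
    am, dm, ap, be, dr, dc, kb = (
        p["alpha_m"], p["delta_m"], p["alpha_p"], p["beta"], p["delta_r"],
        p["delta_c"], p["kb"],
    )
    if variant == "full":
        kf = kb / K_d
        return ReactionNetwork(
            species=["A", "R", "AR", "M", "P1", "P2", "P3"],
            initial={"A": A_T, "R": 0, "AR": 0, "M": 0, "P1": 0, "P2": 0, "P3": 0},
            reactions=[
                Reaction("transcribe", {"M": +1}, am, modifiers={"A": 1}),
                Reaction("decay_M", {"M": -1}, dm, reactants={"M": 1}),
                Reaction("translate", {"P1": +1}, ap, modifiers={"M": 1}),
                Reaction("mature_1", {"P1": -1, "P2": +1}, be, reactants={"P1": 1}),
                Reaction("mature_2", {"P2": -1, "P3": +1}, be, reactants={"P2": 1}),
                Reaction("mature_3", {"P3": -1, "R": +1}, be, reactants={"P3": 1}),
                Reaction("bind", {"A": -1, "R": -1, "AR": +1}, kf,
                         reactants={"A": 1, "R": 1}),
                Reaction("unbind", {"A": +1, "R": +1, "AR": -1}, kb,
                         reactants={"AR": 1}),
                Reaction("decay_R", {"R": -1}, dr, reactants={"R": 1}),
                Reaction("decay_AR", {"AR": -1, "A": +1}, dc, reactants={"AR": 1}),
            ],
            conserved_totals=[("A_T", {"A": 1, "AR": 1}, A_T)],
            name="oscillator_full",
            metadata=_meta("full", None, A_T=A_T, K_d=K_d, **p),
        )
    if variant == "reduced":
        pair = dict(total=float(A_T), partner="Rt", K_d=K_d,
                    estimator=estimator, pair_name="AR")
        return ReactionNetwork(
            species=["Rt", "M", "P1", "P2", "P3"],
            initial={"Rt": 0, "M": 0, "P1": 0, "P2": 0, "P3": 0},
            reactions=[
                Reaction("transcribe", {"M": +1}, am,
                         qssa=QssaTerm(role="unbound", **pair)),
                Reaction("decay_M", {"M": -1}, dm, reactants={"M": 1}),
                Reaction("translate", {"P1": +1}, ap, modifiers={"M": 1}),
                Reaction("mature_1", {"P1": -1, "P2": +1}, be, reactants={"P1": 1}),
                Reaction("mature_2", {"P2": -1, "P3": +1}, be, reactants={"P2": 1}),
                Reaction("mature_3", {"P3": -1, "Rt": +1}, be, reactants={"P3": 1}),
                Reaction("decay_Rt_free", {"Rt": -1}, dr,
                         qssa=QssaTerm(role="partner", **pair)),
                Reaction("decay_Rt_complex", {"Rt": -1}, dc,
                         qssa=QssaTerm(role="complex", **pair)),
            ],
            name="oscillator_reduced",
            metadata=_meta("reduced", estimator, A_T=A_T, K_d=K_d, **p),
        )
    raise ValueError(f"variant must be full|reduced, got {variant!r}")


def make_bistable_switch(
    variant: str,
    B_T: int = 6,
    K_d: float = 1e-3,
    estimator: str = "stqssa",
    **slow_rates,
) -> ReactionNetwork:
    """Bistable switch for mitotic activation of cyclin B/Cdc2.

    Inactive P is activated to M through a basal channel (rate k0 per P)
    and a positive-feedback channel mediated by free M (rate k1 per P per
    free M, the Cdc25 loop collapsed to its equilibrated form); Suc1 (B)
    sequesters M into the inactive complex M:B, and all active forms
    (M and M:B) revert to P at the common rate delta.  Total active
    M_T = M + M:B is bimodal with modes separated by M_T = B_T in the
    tight-binding regime.  The reduced variant keeps (M_T, P) and
    evaluates free M with a QSSA estimator at the current (M_T, B_T).
    """
    p = {**BISTABLE_DEFAULTS, **slow_rates}
    k0, k1, de, c_t, kb = p["k0"], p["k1"], p["delta"], p["C_T"], p["kb"]
    if variant == "full":
        kf = kb / K_d
        return ReactionNetwork(
            species=["P", "M", "B", "MB"],
            initial={"P": c_t, "M": 0, "B": B_T, "MB": 0},
            reactions=[
                Reaction("activate_basal", {"P": -1, "M": +1}, k0,
                         reactants={"P": 1}),
                Reaction("activate_feedback", {"P": -1, "M": +1}, k1,
                         reactants={"P": 1}, modifiers={"M": 1}),
                Reaction("inactivate_free", {"M": -1, "P": +1}, de,
                         reactants={"M": 1}),
                Reaction("inactivate_complex", {"MB": -1, "B": +1, "P": +1}, de,
                         reactants={"MB": 1}),
                Reaction("bind", {"M": -1, "B": -1, "MB": +1}, kf,
                         reactants={"M": 1, "B": 1}),
                Reaction("unbind", {"M": +1, "B": +1, "MB": -1}, kb,
                         reactants={"MB": 1}),
            ],
            conserved_totals=[
                ("C_T", {"P": 1, "M": 1, "MB": 1}, c_t),
                ("B_T", {"B": 1, "MB": 1}, B_T),
            ],
            name="bistable_switch_full",
            metadata=_meta("full", None, B_T=B_T, K_d=K_d, **p),
        )
    if variant == "reduced":
        return ReactionNetwork(
            species=["Mt", "P"],
            initial={"Mt": 0, "P": c_t},
            reactions=[
                Reaction("activate_basal", {"Mt": +1, "P": -1}, k0,
                         reactants={"P": 1}),
                Reaction("activate_feedback", {"Mt": +1, "P": -1}, k1,
                         reactants={"P": 1},
                         qssa=QssaTerm(total="Mt", partner=float(B_T), K_d=K_d,
                                       role="unbound", estimator=estimator,
                                       pair_name="MB")),
                Reaction("inactivate", {"Mt": -1, "P": +1}, de,
                         reactants={"Mt": 1}),
            ],
            conserved_totals=[("C_T", {"Mt": 1, "P": 1}, c_t)],
            name="bistable_switch_reduced",
            metadata=_meta("reduced", estimator, B_T=B_T, K_d=K_d, **p),
        )
    raise ValueError(f"variant must be full|reduced, got {variant!r}")
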