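"""Closed-form assay quantifications.

Relative qPCR expression (Livak ddCt), RIP enrichment normalised to IgG,
input and a reference mRNA, polysome translational efficiency (heavy
polysome over total), luciferase reporter ratios, and clonogenic plating
efficiency / survival fraction.

Ct conventions: a lower cycle threshold means more template; one cycle is a
factor of ``efficiency`` (2 for a perfectly efficient PCR). The default fold
change is the conventional 2^(-ddCt); a ``literal_sign`` flag gives the
2^(+ddCt) variant for compatibility with sources that print the formula
without the minus sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CtRecord:
    sample: str
    gene: str
    condition: str
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"invalid Ct {self.ct}")


@dataclass(frozen=True)
class PolysomeQuant:
    """Relative mRNA amounts in pooled non-polysomal (NP), light (LP) and
    heavy (HP) polysomal fractions."""

    np_amount: float
    lp_amount: float
    hp_amount: float

    def __post_init__(self) -> None:
        amounts = (self.np_amount, self.lp_amount, self.hp_amount)
        if any(a < 0 for a in amounts):
            raise ValueError("fraction amounts must be non-negative")
        if sum(amounts) <= 0:
            raise ValueError("total fraction amount must be > 0")


def ddct_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
    literal_sign: bool = False,
) -> float:
    """Relative expression fold change from four Ct values.

    dCt = Ct(target) - Ct(reference) per condition;
    ddCt = dCt(treated) - dCt(control); fold = 2^(-ddCt) by default.
    """
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (ddct if literal_sign else -ddct)


def rip_enrichment(
    table: pd.DataFrame, reference_gene: str, efficiency: float = 2.0
) -> pd.Series:
    """Per-gene RIP enrichment normalised to IgG, input and a reference mRNA.

    ``table`` needs columns gene, ct_ip, ct_igg, ct_input. Per gene,
    E = eff^(ct_input - ct_ip) / eff^(ct_input - ct_igg) = eff^(ct_igg - ct_ip);
    the reported value is E_gene / E_reference.
    """
    required = {"gene", "ct_ip", "ct_igg", "ct_input"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RIP table missing columns: {sorted(missing)}")
    if table[["ct_ip", "ct_igg", "ct_input"]].isna().any().any():
        raise ValueError("missing IgG/IP/input Ct value")
    df = table.set_index("gene")
    if reference_gene not in df.index:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    enrichment = efficiency ** (df["ct_input"] - df["ct_ip"]) / efficiency ** (
        df["ct_input"] - df["ct_igg"]
    )
    return enrichment / enrichment.loc[reference_gene]


def polysome_te(q: PolysomeQuant, control: PolysomeQuant | None = None):
    """Translational efficiency TE = HP / (NP + LP + HP); with a paired
    control, also the ratio TE_condition / TE_control."""
    te = q.hp_amount / (q.np_amount + q.lp_amount + q.hp_amount)
    if control is None:
        return te
    te_ctrl = polysome_te(control)
    return te, te / te_ctrl


def reporter_ratio(
    rluc: float, fluc: float, control: tuple[float, float] | None = None
) -> float:
    """Renilla/Firefly luciferase ratio, optionally normalised to a control
    (rluc, fluc) pair."""
    if fluc <= 0:
        raise ValueError("Firefly activity must be > 0")
    ratio = rluc / fluc
    if control is None:
        return ratio
    return ratio / reporter_ratio(*control)


def clonogenic_survival(
    colonies: float, plated: float, control_pe: float | None = None
):
    """Plating efficiency (%) = colonies / cells plated x 100; with a control
    PE, also the survival fraction PE / PE_control."""
    if plated <= 0:
        raise ValueError("cells plated must be > 0")
    if colonies < 0:
        raise ValueError("colony count must be >= 0")
    pe = colonies / plated * 100.0
    if control_pe is None:
        return pe
    if control_pe <= 0:
        raise ValueError("control plating efficiency must be > 0")
    return pe, pe / control_pe
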