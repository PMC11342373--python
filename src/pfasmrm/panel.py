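"""Analyte panel: the 20-PFAS target list, MRM transitions and internal-standard map.

The panel bundles everything the downstream stages need to know about the
measurement channels: which precursor→product transitions belong to which
analyte, which transition is the quantifier, which isotopically labeled
internal standard (IS) corrects each analyte, and the expected retention
times used for peak finding and relative-retention-time (RRT) confirmation.

The m/z values and per-channel ion fractions shipped by
:func:`build_default_panel` are editable fixture data chosen from commonly
published PFAS MRM transitions; they carry no quantitative claim and can be
replaced wholesale for a real instrument method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TransitionDef",
    "AnalytePanel",
    "build_default_panel",
    "EFSA4",
    "ROLE_QUANTIFIER",
    "ROLE_QUALIFIER",
    "ROLE_PSEUDO",
]

ROLE_QUANTIFIER = "quantifier"
ROLE_QUALIFIER = "qualifier"
ROLE_PSEUDO = "pseudo"
_ROLES = {ROLE_QUANTIFIER, ROLE_QUALIFIER, ROLE_PSEUDO}

#: The four PFASs covered by the EFSA tolerable-weekly-intake sum.
EFSA4 = ("PFOA", "PFNA", "PFHxS", "PFOS")


@dataclass(frozen=True)
class TransitionDef:
    """One MRM channel (precursor → product ion) of an analyte.

    ``true_ion_fraction`` is the fraction of the analyte's total ion current
    carried by this channel; the simulator uses it to apportion signal and
    the qualifier/quantifier fraction ratio fixes the theoretical ion ratio.
    A ``pseudo`` transition monitors the precursor at low collision energy
    (product m/z equals precursor m/z) and stands in for a second product
    ion for single-product analytes.
    """

    analyte_id: str
    precursor_mz: float
    product_mz: float
    role: str
    true_ion_fraction: float

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown transition role {self.role!r}")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.product_mz > self.precursor_mz:
            raise ValueError("product_mz cannot exceed precursor_mz")
        if self.role == ROLE_PSEUDO and self.product_mz != self.precursor_mz:
            raise ValueError("pseudo transition must have product_mz == precursor_mz")
        if not 0 < self.true_ion_fraction <= 1:
            raise ValueError("true_ion_fraction must lie in (0, 1]")

    @property
    def transition_id(self) -> str:
        return f"{self.analyte_id}_{self.precursor_mz:g}>{self.product_mz:g}"


@dataclass
class AnalytePanel:
    """Target analytes, their MRM transitions, IS assignments and retention times.

    ``analytes`` maps analyte id → chain class (``carboxylate`` / ``sulfonate``
    / ``other``); ``is_map`` maps each analyte to exactly one internal
    standard id; ``injection_standards`` are added just before injection and
    map to no internal standard. Internal and injection standards also carry
    a quantifier transition (they are measured channels).
    """

    analytes: dict[str, str]
    transitions: list[TransitionDef]
    is_map: dict[str, str]
    injection_standards: list[str]
    expected_rt: dict[str, float]
    #: labeled standard id → the analyte it is the isotopologue of (they
    #: co-elute, so they share retention-time jitter); analytes map to
    #: themselves implicitly
    co_elution: dict[str, str] = field(default_factory=dict)

    def elution_group(self, compound_id: str) -> str:
        """Key identifying compounds that physically co-elute."""
        return self.co_elution.get(compound_id, compound_id)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------------

    def transitions_of(self, compound_id: str) -> list[TransitionDef]:
        return [t for t in self.transitions if t.analyte_id == compound_id]

    def quantifier(self, compound_id: str) -> TransitionDef:
        for t in self.transitions_of(compound_id):
            if t.role == ROLE_QUANTIFIER:
                return t
        raise KeyError(f"no quantifier transition for {compound_id!r}")

    def qualifier(self, compound_id: str) -> TransitionDef | None:
        """Second diagnostic channel: a qualifier, else a pseudo transition, else None."""
        trs = self.transitions_of(compound_id)
        for role in (ROLE_QUALIFIER, ROLE_PSEUDO):
            for t in trs:
                if t.role == role:
                    return t
        return None

    def internal_standard_ids(self) -> list[str]:
        return sorted(set(self.is_map.values()))

    def transition_index(self) -> dict[str, TransitionDef]:
        return {t.transition_id: t for t in self.transitions}

    def single_product_analytes(self) -> list[str]:
        """Analytes whose second channel is a pseudo (precursor) transition."""
        out = []
        for a in self.analytes:
            roles = {t.role for t in self.transitions_of(a)}
            if ROLE_PSEUDO in roles and ROLE_QUALIFIER not in roles:
                out.append(a)
        return out

    # -- consistency ---------------------------------------------------------

    def validate(self) -> None:
        measured = {t.analyte_id for t in self.transitions}
        for a in self.analytes:
            trs = self.transitions_of(a)
            n_quant = sum(t.role == ROLE_QUANTIFIER for t in trs)
            if n_quant != 1:
                raise ValueError(f"{a}: expected exactly one quantifier, got {n_quant}")
            frac = sum(t.true_ion_fraction for t in trs)
            if frac > 1 + 1e-9:
                raise ValueError(f"{a}: ion fractions sum to {frac:.3f} > 1")
            if a not in self.is_map:
                raise ValueError(f"{a}: no internal-standard assignment")
            if self.is_map[a] not in measured:
                raise ValueError(f"{a}: internal standard {self.is_map[a]!r} has no transition")
        for inj in self.injection_standards:
            if inj in self.is_map:
                raise ValueError(f"injection standard {inj!r} must not map to an IS")
        for cid in measured:
            if cid not in self.expected_rt:
                raise ValueError(f"{cid}: no expected retention time")


# ---------------------------------------------------------------------------
# Default 20-analyte panel (fixture m/z values, editable)
# ---------------------------------------------------------------------------

# analyte id → (class, precursor, quantifier product, qualifier product or None,
#               quant fraction, qual fraction, RT min)
_ANALYTES: dict[str, tuple[str, float, float, float | None, float, float, float]] = {
    # perfluoroalkyl carboxylic acids (C5–C14)
    "PFPeA":        ("carboxylate", 263.0, 219.0, None,  0.70, 0.10, 2.10),
    "PFHxA":        ("carboxylate", 313.0, 269.0, 119.0, 0.65, 0.18, 3.05),
    "PFHpA":        ("carboxylate", 363.0, 319.0, 169.0, 0.64, 0.17, 3.95),
    "PFOA":         ("carboxylate", 413.0, 369.0, 169.0, 0.62, 0.16, 4.80),
    "PFNA":         ("carboxylate", 463.0, 419.0, 219.0, 0.62, 0.15, 5.55),
    "PFDA":         ("carboxylate", 513.0, 469.0, 219.0, 0.60, 0.15, 6.25),
    "PFUnDA":       ("carboxylate", 563.0, 519.0, 269.0, 0.60, 0.14, 6.90),
    "PFDoDA":       ("carboxylate", 613.0, 569.0, 319.0, 0.58, 0.14, 7.50),
    "PFTrDA":       ("carboxylate", 663.0, 619.0, 369.0, 0.58, 0.13, 8.05),
    "PFTeDA":       ("carboxylate", 713.0, 669.0, 419.0, 0.56, 0.13, 8.55),
    # perfluoroalkyl sulfonic acids
    "PFBS":         ("sulfonate",   299.0,  80.0,  99.0, 0.60, 0.20, 2.75),
    "PFHxS":        ("sulfonate",   399.0,  80.0,  99.0, 0.58, 0.20, 4.45),
    "PFHpS":        ("sulfonate",   449.0,  80.0,  99.0, 0.57, 0.19, 5.20),
    # PFOS quantifies on 499>99: the 499>80 channel is shared with the bile
    # acid TDCA, so the less sensitive but more specific channel is primary.
    "PFOS":         ("sulfonate",   499.0,  99.0,  80.0, 0.15, 0.60, 5.90),
    "PFDS":         ("sulfonate",   599.0,  80.0,  99.0, 0.55, 0.18, 7.15),
    # other PFASs
    "PFOSA":        ("other",       498.0,  78.0, 169.0, 0.55, 0.16, 10.20),
    "HFPO-DA":      ("other",       329.0, 169.0, 285.0, 0.55, 0.22, 3.60),
    "DONA":         ("other",       377.0, 251.0,  85.0, 0.60, 0.15, 4.10),
    "9Cl-PF3ONS":   ("other",       531.0, 351.0,  83.0, 0.55, 0.15, 6.55),
    "11Cl-PF3OUdS": ("other",       631.0, 451.0,  83.0, 0.55, 0.14, 7.80),
}

# internal standards: id → (precursor, product, RT source analyte)
_INTERNAL_STANDARDS: dict[str, tuple[float, float, str]] = {
    "13C3-PFPeA":   (266.0, 222.0, "PFPeA"),
    "13C2-PFHxA":   (315.0, 270.0, "PFHxA"),
    "13C4-PFHpA":   (367.0, 322.0, "PFHpA"),
    "13C4-PFOA":    (417.0, 372.0, "PFOA"),
    "13C5-PFNA":    (468.0, 423.0, "PFNA"),
    "13C2-PFDA":    (515.0, 470.0, "PFDA"),
    "13C2-PFUnDA":  (565.0, 520.0, "PFUnDA"),
    "13C2-PFDoDA":  (615.0, 570.0, "PFDoDA"),
    "13C3-PFBS":    (302.0,  80.0, "PFBS"),
    "18O2-PFHxS":   (403.0,  84.0, "PFHxS"),
    "13C4-PFOS":    (503.0,  80.0, "PFOS"),
    "13C3-HFPO-DA": (332.0, 169.0, "HFPO-DA"),
}

# analyte → internal standard. Analytes without their own labeled analogue
# borrow the surrogate closest in retention time / chemistry.
_IS_MAP: dict[str, str] = {
    "PFPeA": "13C3-PFPeA",
    "PFHxA": "13C2-PFHxA",
    "PFHpA": "13C4-PFHpA",
    "PFOA": "13C4-PFOA",
    "PFNA": "13C5-PFNA",
    "PFDA": "13C2-PFDA",
    "PFUnDA": "13C2-PFUnDA",
    "PFDoDA": "13C2-PFDoDA",
    "PFBS": "13C3-PFBS",
    "PFHxS": "18O2-PFHxS",
    "PFOS": "13C4-PFOS",
    "HFPO-DA": "13C3-HFPO-DA",
    # surrogate assignments (retention time was the deciding factor)
    "PFTrDA": "13C2-PFDoDA",
    "PFTeDA": "13C2-PFDoDA",
    "PFHpS": "13C4-PFOS",
    "PFDS": "13C2-PFUnDA",
    "PFOSA": "13C4-PFOS",
    "DONA": "13C4-PFHpA",
    "9Cl-PF3ONS": "13C2-PFDA",
    "11Cl-PF3OUdS": "13C2-PFDoDA",
}

#: Analytes that borrow a surrogate IS because no labeled analogue was available.
SURROGATE_IS_ANALYTES = ("PFTrDA", "PFHpS", "PFDS", "DONA", "9Cl-PF3ONS", "11Cl-PF3OUdS")

_INJECTION_STANDARDS: dict[str, tuple[float, float, str]] = {
    "13C8-PFOA": (421.0, 376.0, "PFOA"),
    "13C8-PFOS": (507.0,  80.0, "PFOS"),
}


def build_default_panel() -> AnalytePanel:
    """Build the default panel: 20 analytes, 12 internal standards, 2 injection standards.

    PFPeA carries a single abundant product ion, so its second channel is a
    precursor→precursor (pseudo) transition acquired at low collision energy;
    identity assessment on that channel deviates from EURL guidance and is
    flagged downstream.
    """
    analytes: dict[str, str] = {}
    transitions: list[TransitionDef] = []
    expected_rt: dict[str, float] = {}

    for aid, (cls, prec, q_prod, ql_prod, f_q, f_ql, rt) in _ANALYTES.items():
        analytes[aid] = cls
        expected_rt[aid] = rt
        transitions.append(TransitionDef(aid, prec, q_prod, ROLE_QUANTIFIER, f_q))
        if ql_prod is None:
            transitions.append(TransitionDef(aid, prec, prec, ROLE_PSEUDO, f_ql))
        else:
            transitions.append(TransitionDef(aid, prec, ql_prod, ROLE_QUALIFIER, f_ql))

    co_elution: dict[str, str] = {}
    for sid, (prec, prod, src) in _INTERNAL_STANDARDS.items():
        transitions.append(TransitionDef(sid, prec, prod, ROLE_QUANTIFIER, 0.6))
        expected_rt[sid] = _ANALYTES[src][6]
        co_elution[sid] = src
    for sid, (prec, prod, src) in _INJECTION_STANDARDS.items():
        transitions.append(TransitionDef(sid, prec, prod, ROLE_QUANTIFIER, 0.6))
        expected_rt[sid] = _ANALYTES[src][6]
        co_elution[sid] = src

    return AnalytePanel(
        analytes=analytes,
        transitions=transitions,
        is_map=dict(_IS_MAP),
        injection_standards=list(_INJECTION_STANDARDS),
        expected_rt=expected_rt,
        co_elution=co_elution,
    )
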