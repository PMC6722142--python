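"""Mass-action reaction networks for HER2 membrane trafficking.

The two model variants are built from explicit reaction lists rather than
hand-written differential equations; the reaction list is the single source
of truth from which both the piecewise-linear system matrices and the full
right-hand side (including the free-ligand bookkeeping) are compiled.

Species naming
--------------
Receptors carry a location tag (``m`` membrane / ``i`` internal for the
single-population model; region tags ``R`` ruffled / ``F`` flat plus an
``i`` prefix for internalized pools in the two-region model) and ligation
suffixes ``_T`` (trastuzumab bound) and ``_A`` (Affibody label bound).
``T`` and ``A`` denote the free compound amounts in the medium.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

LIGANDS = ("T", "A")

#: receptor species, fixed state ordering per model variant
RECEPTOR_SPECIES = {
    "A": (
        "N_m", "N_i", "N_m_T", "N_i_T",
        "N_m_A", "N_m_TA", "N_i_A", "N_i_TA",
    ),
    "B": (
        "N_R", "N_iR", "N_R_T", "N_iR_T",
        "N_R_A", "N_R_TA", "N_iR_A", "N_iR_TA",
        "N_F", "N_iF", "N_F_T", "N_iF_T",
        "N_F_A", "N_F_TA", "N_iF_A", "N_iF_TA",
    ),
}

#: membrane-resident receptor species (any ligation state)
MEMBRANE_SPECIES = {
    "A": ("N_m", "N_m_T", "N_m_A", "N_m_TA"),
    "B": ("N_R", "N_R_T", "N_R_A", "N_R_TA",
          "N_F", "N_F_T", "N_F_A", "N_F_TA"),
}

#: species contributing to the fluorescence observable (label-bound, membrane)
OBSERVED_SPECIES = {
    "A": ("N_m_A", "N_m_TA"),
    "B": ("N_R_A", "N_R_TA", "N_F_A", "N_F_TA"),
}


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``substrates``/``products`` list species names; the free-ligand species
    ``"T"``/``"A"`` may appear on either side (binding consumes the free
    pool, membrane dissociation releases into it, intracellular dissociation
    does not release — the compound is lost from the tracked pools).
    ``rate`` names the elementary rate constant (1/min; for bimolecular
    reactions per amount unit per minute, for production amount/min).
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    rate: str

    @property
    def receptor_substrate(self) -> str | None:
        for s in self.substrates:
            if s not in LIGANDS:
                return s
        return None

    @property
    def ligand_substrates(self) -> tuple[str, ...]:
        return tuple(s for s in self.substrates if s in LIGANDS)


def model_a_reactions() -> tuple[Reaction, ...]:
    """Reaction list for the single-population recycling model."""
    R = Reaction
    return (
        # constitutive trafficking
        R("production", (), ("N_m",), "k_prod"),
        R("basal_internalization", ("N_m",), ("N_i",), "k_int"),
        R("basal_internalization_A", ("N_m_A",), ("N_i_A",), "k_int"),
        R("basal_recycling", ("N_i",), ("N_m",), "k_rec"),
        R("basal_recycling_A", ("N_i_A",), ("N_m_A",), "k_rec"),
        R("degradation", ("N_i",), (), "k_deg"),
        R("degradation_A", ("N_i_A",), (), "k_deg"),
        # drug binding / activation of induced internalization
        R("activation", ("N_m", "T"), ("N_m_T",), "k_act"),
        R("activation_A", ("N_m_A", "T"), ("N_m_TA",), "k_act"),
        R("drug_dissociation_m", ("N_m_T",), ("N_m", "T"), "k_diss"),
        R("drug_dissociation_mA", ("N_m_TA",), ("N_m_A", "T"), "k_diss"),
        R("drug_dissociation_i", ("N_i_T",), ("N_i",), "k_diss"),
        R("drug_dissociation_iA", ("N_i_TA",), ("N_i_A",), "k_diss"),
        # drug-induced trafficking
        R("drug_internalization", ("N_m_T",), ("N_i_T",), "k_int_T"),
        R("drug_internalization_A", ("N_m_TA",), ("N_i_TA",), "k_int_T"),
        R("drug_recycling", ("N_i_T",), ("N_m_T",), "k_rec_T"),
        R("drug_recycling_A", ("N_i_TA",), ("N_m_TA",), "k_rec_T"),
        R("drug_degradation", ("N_i_T",), (), "k_deg_T"),
        R("drug_degradation_A", ("N_i_TA",), (), "k_deg_T"),
        # Affibody label binding (membrane only)
        R("label_binding", ("N_m", "A"), ("N_m_A",), "k_on"),
        R("label_binding_T", ("N_m_T", "A"), ("N_m_TA",), "k_on"),
        R("label_dissociation_m", ("N_m_A",), ("N_m", "A"), "k_off"),
        R("label_dissociation_mT", ("N_m_TA",), ("N_m_T", "A"), "k_off"),
        R("label_dissociation_i", ("N_i_A",), ("N_i",), "k_off"),
        R("label_dissociation_iT", ("N_i_TA",), ("N_i_T",), "k_off"),
    )


def model_b_reactions() -> tuple[Reaction, ...]:
    """Reaction list for the two-membrane-region model.

    Built by systematic product construction over regions {R, F} x ligation
    states. Region-specific rates: activation (``k_act_R``/``k_act_F``) and
    drug-induced internalization (``k_int_RT``/``k_int_FT``), optionally
    drug-induced recycling and degradation; drug dissociation and label
    kinetics are shared between regions. There is no constitutive
    production, internalization, recycling or degradation: those reductions
    from the single-population analysis are carried over, so internalized
    receptors are absorbing apart from ligand dissociation.
    """
    R = Reaction
    rxns: list[Reaction] = []
    for reg in ("R", "F"):
        m, mT = f"N_{reg}", f"N_{reg}_T"
        mA, mTA = f"N_{reg}_A", f"N_{reg}_TA"
        i, iT = f"N_i{reg}", f"N_i{reg}_T"
        iA, iTA = f"N_i{reg}_A", f"N_i{reg}_TA"
        k_act, k_int = f"k_act_{reg}", f"k_int_{reg}T"
        k_rec, k_deg = f"k_rec_{reg}T", f"k_deg_{reg}T"
        rxns += [
            R(f"activation_{reg}", (m, "T"), (mT,), k_act),
            R(f"activation_{reg}A", (mA, "T"), (mTA,), k_act),
            R(f"drug_dissociation_{reg}m", (mT,), (m, "T"), "k_diss"),
            R(f"drug_dissociation_{reg}mA", (mTA,), (mA, "T"), "k_diss"),
            R(f"drug_dissociation_{reg}i", (iT,), (i,), "k_diss"),
            R(f"drug_dissociation_{reg}iA", (iTA,), (iA,), "k_diss"),
            R(f"drug_internalization_{reg}", (mT,), (iT,), k_int),
            R(f"drug_internalization_{reg}A", (mTA,), (iTA,), k_int),
            R(f"drug_recycling_{reg}", (iT,), (mT,), k_rec),
            R(f"drug_recycling_{reg}A", (iTA,), (mTA,), k_rec),
            R(f"drug_degradation_{reg}", (iT,), (), k_deg),
            R(f"drug_degradation_{reg}A", (iTA,), (), k_deg),
            R(f"label_binding_{reg}", (m, "A"), (mA,), "k_on"),
            R(f"label_binding_{reg}T", (mT, "A"), (mTA,), "k_on"),
            R(f"label_dissociation_{reg}m", (mA,), (m, "A"), "k_off"),
            R(f"label_dissociation_{reg}mT", (mTA,), (mT, "A"), "k_off"),
            R(f"label_dissociation_{reg}i", (iA,), (i,), "k_off"),
            R(f"label_dissociation_{reg}iT", (iTA,), (iT,), "k_off"),
        ]
    return tuple(rxns)


class Network:
    """Compiled reaction network for one model variant.

    Provides the piecewise-linear receptor system (free-ligand amounts held
    at their switch-determined values, under which the receptor dynamics are
    exactly linear) and the full nonlinear right-hand side in which the free
    compounds are integrated states with the printed consumption terms.
    """

    def __init__(self, model: str):
        if model not in RECEPTOR_SPECIES:
            raise ValueError(f"unknown model variant {model!r}")
        self.model = model
        self.receptors = RECEPTOR_SPECIES[model]
        self.species = self.receptors + LIGANDS
        self.reactions = (model_a_reactions() if model == "A"
                          else model_b_reactions())
        self.index = {s: i for i, s in enumerate(self.species)}
        self.n_receptors = len(self.receptors)
        # precompile (rate key, ligand keys, substrate idx, net stoichiometry)
        self._compiled = []
        for rx in self.reactions:
            stoich = np.zeros(len(self.species))
            for s in rx.substrates:
                stoich[self.index[s]] -= 1.0
            for s in rx.products:
                stoich[self.index[s]] += 1.0
            sub = rx.receptor_substrate
            self._compiled.append((
                rx.rate,
                rx.ligand_substrates,
                None if sub is None else self.index[sub],
                stoich,
            ))

    # ------------------------------------------------------------------
    def linear_system(self, rates: dict, ligand_amounts: dict
                      ) -> tuple[np.ndarray, np.ndarray]:
        """System matrix and constant term of the receptor subsystem.

        With the free-compound amounts fixed (switch semantics
        ``T = N_T * s_on``), receptor dynamics obey ``dx/dt = M x + b``
        where ``b`` carries the zeroth-order production flux.
        """
        n = self.n_receptors
        M = np.zeros((n, n))
        b = np.zeros(n)
        for rate_key, ligs, sub, stoich in self._compiled:
            k = rates[rate_key]
            for lig in ligs:
                k = k * ligand_amounts[lig]
            if k == 0.0:
                continue
            if sub is None:
                b += k * stoich[:n]
            else:
                M[:, sub] += k * stoich[:n]
        return M, b

    def rhs_full(self, x: np.ndarray, rates: dict,
                 s_on_T: float, s_on_A: float) -> np.ndarray:
        """Time derivative of the full state (receptors + free T and A).

        Fluxes involving a free compound use its gated amount
        (``T * s_on_T``); the free-compound derivatives themselves are gated
        so that a washed-out compound stays at zero rather than re-growing
        from dissociating complexes.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.species),):
            raise ValueError(
                f"state must have {len(self.species)} components "
                f"for model {self.model}")
        gate = {"T": s_on_T, "A": s_on_A}
        iT, iA = self.index["T"], self.index["A"]
        dx = np.zeros_like(x)
        for rate_key, ligs, sub, stoich in self._compiled:
            flux = rates[rate_key]
            if sub is not None:
                flux = flux * x[sub]
            for lig in ligs:
                flux = flux * x[self.index[lig]] * gate[lig]
            if flux == 0.0:
                continue
            dx += flux * stoich
        dx[iT] *= s_on_T
        dx[iA] *= s_on_A
        return dx


@lru_cache(maxsize=None)
def get_network(model: str) -> Network:
    return Network(model)
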