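"""Biochemical reaction networks with mass-action kinetics.

The central object is :class:`NetworkModel`: an ordered collection of species
and reactions describing a single well-mixed membrane compartment.  Reactions
come in three forms,

* reversible binding            ``A + B <-> AB``
* two-step catalysis            ``A + E <-> AE -> P + E``
* first-order conversion        ``A -> B``

and are written in a compact text grammar (UTF-8 arrows ``↔``/``→`` or ASCII
``<->``/``->``).  Leading integers in a species token are stoichiometric
coefficients, so ``2cAMP`` means two molecules of ``cAMP``.

Units are nM for concentrations and s^-1 for first-order rates; association
rates ``kon`` carry nM^-(n-1) s^-1 for an n-th order step.  The packaged
default model is the beta-2 adrenergic receptor -> Gs/Gi -> AC6 -> cAMP ->
PKA -> VASP phosphorylation cascade of a mouse-embryonic-fibroblast
submembrane compartment, with the ligand ISO (``L``) as the clamped input and
phosphorylated VASP (``pVASP``) as the output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "NetworkModel",
    "ParameterVector",
    "ModelValidationError",
    "ReactionParseError",
    "load_model",
    "load_default_model",
    "save_model",
    "mass_action_rhs",
    "conserved_moieties",
    "apply_parameters",
    "derived_constants",
]

REV_ARROWS = ("↔", "<->", "<=>")
FWD_ARROWS = ("→", "-->", "->")

DEFAULT_INPUT = "L"
DEFAULT_OUTPUT = "pVASP"


class ModelValidationError(ValueError):
    """A model or parameter assignment violates a structural constraint."""


class ReactionParseError(ValueError):
    """A reaction string could not be parsed."""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species.

    Parameters
    ----------
    name : str
        Unique identifier within the model.
    initial_conc : float
        Initial concentration in nM (>= 0).
    clamped : bool
        Held constant during simulation (the extracellular input).
    is_michaelis_complex : bool
        Transient enzyme-substrate complex of a two-step catalytic
        reaction.  These are excluded from the "molecular species" count.
    """

    name: str
    initial_conc: float = 0.0
    clamped: bool = False
    is_michaelis_complex: bool = False

    def __post_init__(self) -> None:
        if self.initial_conc < 0:
            raise ModelValidationError(
                f"species {self.name!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class ReactionDef:
    """A reaction in one of the three supported forms.

    ``reactants`` and ``products`` are tuples of ``(species, stoichiometry)``
    with positive integer stoichiometries.  ``complex_species`` is the bound
    intermediate of binding/catalytic forms (None for conversions).
    """

    reactants: tuple[tuple[str, int], ...]
    complex_species: str | None
    products: tuple[tuple[str, int], ...]
    kon: float | None
    koff: float | None
    kcat: float | None
    form: str  # reversible_binding | catalytic | conversion
    name: str = ""

    def __post_init__(self) -> None:
        for sp, st in (*self.reactants, *self.products):
            if st < 1 or int(st) != st:
                raise ModelValidationError(
                    f"reaction {self.name!r}: stoichiometry of {sp} must be a "
                    "positive integer"
                )
        for label, val in (("kon", self.kon), ("koff", self.koff), ("kcat", self.kcat)):
            if val is not None and val < 0:
                raise ModelValidationError(
                    f"reaction {self.name!r}: negative rate {label}={val}"
                )
        expected = {
            "reversible_binding": (True, True, False),
            "catalytic": (True, True, True),
            "conversion": (False, False, True),
        }
        if self.form not in expected:
            raise ModelValidationError(f"unknown reaction form {self.form!r}")
        need = expected[self.form]
        have = tuple(v is not None for v in (self.kon, self.koff, self.kcat))
        if have != need:
            raise ModelValidationError(
                f"reaction {self.name!r} ({self.form}): rates set {have}, "
                f"expected pattern (kon, koff, kcat)={need}"
            )

    def rate_names(self) -> tuple[str, ...]:
        return tuple(
            n for n, v in (("kon", self.kon), ("koff", self.koff), ("kcat", self.kcat))
            if v is not None
        )


@dataclass
class NetworkModel:
    """A mass-action reaction network with a designated input and output."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    input_species: str = DEFAULT_INPUT
    output_species: str = DEFAULT_OUTPUT

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate species names: {dup}")
        self._index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            refs = [sp for sp, _ in (*rxn.reactants, *rxn.products)]
            if rxn.complex_species is not None:
                refs.append(rxn.complex_species)
            for sp in refs:
                if sp not in self._index:
                    raise ModelValidationError(
                        f"reaction {rxn.name!r} references unknown species {sp!r}"
                    )
        self._kinetics = None

    # -- basic queries ----------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no species named {name!r}") from None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_molecular_species(self) -> int:
        """Species count excluding transient Michaelis complexes."""
        return sum(not s.is_michaelis_complex for s in self.species)

    @property
    def n_nonzero_initial(self) -> int:
        return sum(s.initial_conc > 0 for s in self.species)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    @property
    def clamped_mask(self) -> np.ndarray:
        return np.array([s.clamped for s in self.species], dtype=bool)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            species=list(self.species),
            reactions=list(self.reactions),
            input_species=self.input_species,
            output_species=self.output_species,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.input_species == other.input_species
            and self.output_species == other.output_species
        )

    # -- compiled kinetics -------------------------------------------------

    @property
    def kinetics(self) -> "CompiledKinetics":
        if self._kinetics is None:
            self._kinetics = CompiledKinetics(self)
        return self._kinetics

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.kinetics.rhs(t, y)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.kinetics.jac(t, y)


class CompiledKinetics:
    """Index arrays for fast mass-action flux evaluation.

    Every reaction is decomposed into irreversible elementary steps
    (binding, unbinding, catalysis, conversion).  Step ``j`` has flux
    ``k[j] * prod_i y[i]**s_ij`` over its consumed species; the state
    derivative is ``N @ flux`` with ``N`` the net stoichiometry matrix,
    rows of clamped species zeroed.
    """

    def __init__(self, model: NetworkModel):
        n_sp = model.n_species
        idx = model.species_index
        steps: list[tuple[float, list[tuple[int, int]], list[tuple[int, int]]]] = []
        for rxn in model.reactions:
            reac = [(idx(sp), st) for sp, st in rxn.reactants]
            prod = [(idx(sp), st) for sp, st in rxn.products]
            if rxn.form == "conversion":
                steps.append((rxn.kcat, reac, prod))
                continue
            comp = [(idx(rxn.complex_species), 1)]
            steps.append((rxn.kon, reac, comp))
            steps.append((rxn.koff, comp, reac))
            if rxn.form == "catalytic":
                steps.append((rxn.kcat, comp, prod))

        n_steps = len(steps)
        self.n_steps = n_steps
        self.k = np.array([s[0] for s in steps], dtype=float)
        # up to two distinct consumed species per step; pad with a virtual
        # species index n_sp whose value is fixed at 1
        self.i1 = np.full(n_steps, n_sp, dtype=np.intp)
        self.p1 = np.zeros(n_steps)
        self.i2 = np.full(n_steps, n_sp, dtype=np.intp)
        self.p2 = np.zeros(n_steps)
        N = np.zeros((n_sp, n_steps))
        for j, (_, reac, prod) in enumerate(steps):
            if len(reac) > 2:
                raise ModelValidationError(
                    "more than two distinct reactant species in one step"
                )
            self.i1[j], self.p1[j] = reac[0]
            if len(reac) == 2:
                self.i2[j], self.p2[j] = reac[1]
            for i, st in reac:
                N[i, j] -= st
            for i, st in prod:
                N[i, j] += st
        self.N_full = N.copy()
        N = N.copy()
        N[model.clamped_mask, :] = 0.0
        self.N = N
        self._yext = np.ones(n_sp + 1)

    def flux(self, y: np.ndarray) -> np.ndarray:
        ye = self._yext
        ye[:-1] = y
        return self.k * ye[self.i1] ** self.p1 * ye[self.i2] ** self.p2

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        # slightly negative trial states occur inside the stiff solver;
        # mass-action fluxes evaluated on the raw state are self-restoring
        # (consumption of a negative species reverses sign), so no clipping
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={t}")
        return self.N @ self.flux(y)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._yext
        ye[:-1] = y
        f1 = ye[self.i1] ** self.p1
        f2 = ye[self.i2] ** self.p2
        with np.errstate(divide="ignore", invalid="ignore"):
            d1 = np.where(self.p1 > 0, self.p1 * ye[self.i1] ** (self.p1 - 1), 0.0)
            d2 = np.where(self.p2 > 0, self.p2 * ye[self.i2] ** (self.p2 - 1), 0.0)
        d1 = np.nan_to_num(d1, posinf=0.0)
        d2 = np.nan_to_num(d2, posinf=0.0)
        n_sp = self.N.shape[0]
        D = np.zeros((self.n_steps, n_sp + 1))
        rows = np.arange(self.n_steps)
        np.add.at(D, (rows, self.i1), self.k * d1 * f2)
        np.add.at(D, (rows, self.i2), self.k * f1 * d2)
        return self.N @ D[:, :n_sp]


# -- parsing ---------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(\d+)?(.+)$")


def _parse_species_token(token: str) -> tuple[str, int]:
    """``'2cAMP' -> ('cAMP', 2)``; a bare name has coefficient 1."""
    token = token.strip()
    if not token:
        raise ReactionParseError("empty species token")
    m = _TOKEN_RE.match(token)
    coeff = int(m.group(1)) if m.group(1) else 1
    name = m.group(2).strip()
    if not name:
        raise ReactionParseError(f"species token {token!r} has no name")
    return name, coeff


def _split_side(side: str) -> tuple[tuple[str, int], ...]:
    return tuple(_parse_species_token(t) for t in side.split("+"))


def _split_once(text: str, arrows: Iterable[str]) -> tuple[str, str] | None:
    for arrow in arrows:
        if arrow in text:
            left, right = text.split(arrow, 1)
            return left, right
    return None


def parse_reaction(
    reaction_string: str,
    kon: float | None,
    koff: float | None,
    kcat: float | None,
) -> ReactionDef:
    """Parse one reaction-grammar string into a :class:`ReactionDef`.

    Grammar: ``A + B ↔ C → D + E`` (catalytic), ``A + B ↔ C`` (reversible
    binding) or ``A → B`` (conversion); ASCII ``<->`` / ``->`` also accepted.
    """
    text = reaction_string.strip()
    rev = _split_once(text, REV_ARROWS)
    if rev is not None:
        left, rest = rev
        fwd = _split_once(rest, FWD_ARROWS)
        if fwd is not None:
            comp_part, prod_part = fwd
            comp, ccoeff = _parse_species_token(comp_part)
            if ccoeff != 1:
                raise ReactionParseError(
                    f"{reaction_string!r}: complex coefficient must be 1"
                )
            return ReactionDef(
                reactants=_split_side(left),
                complex_species=comp,
                products=_split_side(prod_part),
                kon=kon, koff=koff, kcat=kcat,
                form="catalytic", name=text,
            )
        comp, ccoeff = _parse_species_token(rest)
        if ccoeff != 1:
            raise ReactionParseError(
                f"{reaction_string!r}: complex coefficient must be 1"
            )
        if kcat is not None:
            raise ReactionParseError(
                f"{reaction_string!r}: kcat given for a pure binding reaction"
            )
        return ReactionDef(
            reactants=_split_side(left),
            complex_species=comp,
            products=(),
            kon=kon, koff=koff, kcat=None,
            form="reversible_binding", name=text,
        )
    fwd = _split_once(text, FWD_ARROWS)
    if fwd is None:
        raise ReactionParseError(f"no arrow found in {reaction_string!r}")
    left, right = fwd
    if kon is not None or koff is not None:
        raise ReactionParseError(
            f"{reaction_string!r}: conversion reactions take only kcat"
        )
    return ReactionDef(
        reactants=_split_side(left),
        complex_species=None,
        products=_split_side(right),
        kon=None, koff=None, kcat=kcat,
        form="conversion", name=text,
    )


def _canonical_name(rxn: ReactionDef) -> str:
    def side(terms):
        return " + ".join(
            (f"{st}{sp}" if st > 1 else sp) for sp, st in terms
        )
    if rxn.form == "conversion":
        return f"{side(rxn.reactants)} → {side(rxn.products)}"
    base = f"{side(rxn.reactants)} ↔ {rxn.complex_species}"
    if rxn.form == "catalytic":
        base += f" → {side(rxn.products)}"
    return base


def load_model(
    reaction_table,
    concentration_table,
    input_species: str = DEFAULT_INPUT,
    output_species: str = DEFAULT_OUTPUT,
) -> NetworkModel:
    """Build a :class:`NetworkModel` from a reaction and a concentration table.

    Parameters
    ----------
    reaction_table : path or file-like
        TSV with columns ``reaction_string, kon, koff, kcat``.
    concentration_table : path or file-like
        TSV with columns ``species, conc0_nM``.  Species that appear only in
        reactions start at 0 nM.
    input_species, output_species : str
        The clamped extracellular input and the read-out species.
    """
    rdf = pd.read_csv(reaction_table, sep="\t", dtype={"reaction_string": str})
    cdf = pd.read_csv(concentration_table, sep="\t")
    for col in ("kon", "koff", "kcat"):
        if col not in rdf.columns:
            rdf[col] = np.nan

    reactions: list[ReactionDef] = []
    order: list[str] = []
    seen: set[str] = set()
    michaelis: set[str] = set()

    def note(name: str) -> None:
        if name not in seen:
            seen.add(name)
            order.append(name)

    for row_no, row in enumerate(rdf.itertuples(index=False), start=2):
        rates = [
            None if pd.isna(v) else float(v)
            for v in (row.kon, row.koff, row.kcat)
        ]
        for label, v in zip(("kon", "koff", "kcat"), rates):
            if v is not None and v < 0:
                raise ModelValidationError(
                    f"row {row_no}: negative rate {label}={v}"
                )
        try:
            rxn = parse_reaction(row.reaction_string, *rates)
        except ReactionParseError as exc:
            raise ReactionParseError(f"row {row_no}: {exc}") from exc
        reactions.append(rxn)
        for sp, _ in rxn.reactants:
            note(sp)
        if rxn.complex_species is not None:
            note(rxn.complex_species)
            if rxn.form == "catalytic":
                michaelis.add(rxn.complex_species)
        for sp, _ in rxn.products:
            note(sp)

    conc = {}
    for _, r in cdf.iterrows():
        name = str(r["species"]).strip()
        conc[name] = float(r["conc0_nM"])
        note(name)

    species = [
        SpeciesDef(
            name=n,
            initial_conc=conc.get(n, 0.0),
            clamped=(n == input_species),
            is_michaelis_complex=n in michaelis,
        )
        for n in order
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        input_species=input_species,
        output_species=output_species,
    )


def load_default_model() -> NetworkModel:
    """Load the packaged beta-2AR/cAMP/PKA/pVASP compartment model."""
    data = resources.files(__package__) / "data"
    with resources.as_file(data / "reactions.tsv") as rp, \
            resources.as_file(data / "concentrations.tsv") as cp:
        return load_model(rp, cp)


def save_model(model: NetworkModel, reaction_path, concentration_path) -> None:
    """Write a model back to the two-table TSV format (round-trip safe)."""
    rows = []
    for rxn in model.reactions:
        rows.append(
            {
                "reaction_string": rxn.name or _canonical_name(rxn),
                "kon": rxn.kon,
                "koff": rxn.koff,
                "kcat": rxn.kcat,
            }
        )
    pd.DataFrame(rows).to_csv(reaction_path, sep="\t", index=False)
    crow = [
        {"species": s.name, "conc0_nM": repr(s.initial_conc)}
        for s in model.species
        if s.initial_conc > 0
    ]
    pd.DataFrame(crow).to_csv(concentration_path, sep="\t", index=False)


# -- operations ------------------------------------------------------------


def mass_action_rhs(model: NetworkModel, state: Sequence[float]) -> np.ndarray:
    """Mass-action time derivative (nM/s) at ``state``.

    Reversible binding contributes ``kon*prod[reactant]**stoich - koff*[C]``,
    catalysis adds ``kcat*[C]`` toward the products, conversions contribute
    ``kcat*[substrate]``.  Clamped species have derivative 0.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError(
            f"state length {state.shape} != number of species {model.n_species}"
        )
    return model.rhs(0.0, state)


def conserved_moieties(model: NetworkModel) -> list[tuple[str, dict[str, int]]]:
    """Independent conservation relations of the non-clamped species.

    Computed exactly (rational arithmetic) as the left null space of the
    elementary-step stoichiometry matrix restricted to non-clamped species.
    Returns ``(label, {species: multiplicity})`` pairs; multiplicities are
    scaled to coprime integers.
    """
    free = ~model.clamped_mask
    names = [str(n) for n in np.array(model.species_names)[free]]
    N = model.kinetics.N_full[free, :]
    M = sympy.Matrix(N.astype(int))
    basis = M.T.nullspace()
    if not basis:
        return []
    # canonicalize: RREF of the stacked basis gives one relation per leading
    # species, which for biochemical networks is the familiar "total protein"
    stacked = sympy.Matrix([list(v.T) for v in basis])
    rref, _ = stacked.rref()
    out = []
    for r in range(rref.rows):
        vec = list(rref.row(r))
        if all(v == 0 for v in vec):
            continue
        denoms = [sympy.fraction(x)[1] for x in vec]
        scale = sympy.lcm(denoms)
        ivec = [int(x * scale) for x in vec]
        g = int(np.gcd.reduce([abs(v) for v in ivec if v != 0]))
        ivec = [v // g for v in ivec]
        if sum(ivec) < 0:
            ivec = [-v for v in ivec]
        members = {n: v for n, v in zip(names, ivec) if v != 0}
        anchor = next(n for n, v in members.items() if v != 0)
        out.append((f"total_{anchor}", members))
    return out


def apply_parameters(model: NetworkModel, params: "ParameterVector") -> NetworkModel:
    """Return a new model with the addressed rates/concentrations replaced."""
    reactions = list(model.reactions)
    species = list(model.species)
    sp_index = {s.name: i for i, s in enumerate(species)}
    for (kind, ref, fld), value in params.items():
        if value <= 0 or not np.isfinite(value):
            raise ModelValidationError(
                f"parameter {(kind, ref, fld)}: value must be positive, got {value}"
            )
        if kind == "rate":
            rxn = reactions[ref]
            if getattr(rxn, fld) is None:
                raise ModelValidationError(
                    f"reaction {ref} has no rate {fld!r}"
                )
            reactions[ref] = replace(rxn, **{fld: float(value)})
        elif kind == "conc":
            if ref not in sp_index:
                raise ModelValidationError(f"no species named {ref!r}")
            i = sp_index[ref]
            species[i] = replace(species[i], initial_conc=float(value))
        else:
            raise ModelValidationError(f"unknown parameter kind {kind!r}")
    return NetworkModel(
        species=species,
        reactions=reactions,
        input_species=model.input_species,
        output_species=model.output_species,
    )


def derived_constants(model: NetworkModel) -> pd.DataFrame:
    """Per-reaction dissociation and Michaelis constants (nM).

    ``Kd = koff/kon``; ``KM = (koff + kcat)/kon`` (equal to Kd when there is
    no catalytic step).  Reactions without a kon are skipped.
    """
    import logging

    rows = []
    for i, rxn in enumerate(model.reactions):
        if rxn.kon is None:
            continue
        if rxn.kon == 0:
            logging.getLogger(__name__).warning(
                "reaction %r has kon=0; skipped from Kd/KM table", rxn.name
            )
            continue
        kcat = rxn.kcat if rxn.kcat is not None else 0.0
        rows.append(
            {
                "reaction": rxn.name,
                "reaction_index": i,
                "Kd_nM": rxn.koff / rxn.kon,
                "KM_nM": (rxn.koff + kcat) / rxn.kon,
            }
        )
    return pd.DataFrame(rows, columns=["reaction", "reaction_index", "Kd_nM", "KM_nM"])


# -- parameter vectors -----------------------------------------------------


class ParameterVector:
    """Ordered map from parameter keys to positive values.

    Keys are ``("rate", reaction_index, "kon"|"koff"|"kcat")`` or
    ``("conc", species_name, "conc0")``.  Provides linear and log10 array
    views for optimization, and round-trips losslessly onto a model via
    :func:`apply_parameters`.
    """

    def __init__(self, entries: Mapping[tuple, float]):
        self._keys = list(entries)
        self._values = np.array([entries[k] for k in self._keys], dtype=float)
        if np.any(self._values <= 0) or not np.all(np.isfinite(self._values)):
            bad = [k for k, v in zip(self._keys, self._values) if not v > 0]
            raise ModelValidationError(f"nonpositive parameter values at {bad}")

    @classmethod
    def from_model(
        cls,
        model: NetworkModel,
        subset: str | Sequence[tuple] = "both",
        exclude_species: Sequence[str] = (),
    ) -> "ParameterVector":
        """Extract the free parameters of ``model``.

        ``subset`` is one of ``rates_only``, ``concentrations_only``,
        ``both``, or an explicit list of keys.  Concentration entries cover
        species with nonzero initial concentration that are not clamped.
        """
        entries: dict[tuple, float] = {}
        if not isinstance(subset, str):
            for key in subset:
                kind, ref, fld = key
                if kind == "rate":
                    entries[key] = getattr(model.reactions[ref], fld)
                else:
                    entries[key] = model.species[model.species_index(ref)].initial_conc
            return cls(entries)
        if subset not in ("rates_only", "concentrations_only", "both"):
            raise ValueError(f"unknown parameter subset {subset!r}")
        if subset in ("rates_only", "both"):
            for i, rxn in enumerate(model.reactions):
                for fld in rxn.rate_names():
                    entries[("rate", i, fld)] = getattr(rxn, fld)
        if subset in ("concentrations_only", "both"):
            for s in model.species:
                if s.initial_conc > 0 and not s.clamped and s.name not in exclude_species:
                    entries[("conc", s.name, "conc0")] = s.initial_conc
        return cls(entries)

    # mapping-ish surface
    def items(self):
        return zip(self._keys, self._values)

    def keys(self):
        return list(self._keys)

    def __len__(self) -> int:
        return len(self._keys)

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    @property
    def log10_values(self) -> np.ndarray:
        return np.log10(self._values)

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(dict(zip(self._keys, np.asarray(values, dtype=float))))

    def with_log10_values(self, log_values: np.ndarray) -> "ParameterVector":
        return self.with_values(10.0 ** np.asarray(log_values, dtype=float))

    def scaled(self, multipliers: np.ndarray) -> "ParameterVector":
        return self.with_values(self._values * np.asarray(multipliers, dtype=float))

    def labels(self) -> list[str]:
        out = []
        for kind, ref, fld in self._keys:
            if kind == "rate":
                out.append(f"r{ref}.{fld}")
            else:
                out.append(f"{ref}.conc0")
        return out

    def __repr__(self) -> str:
        return f"ParameterVector({len(self)} entries)"
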