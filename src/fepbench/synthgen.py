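"""Synthetic inputs with known ground truth, plus packaged study fixtures.

Three generators emulate the data every pipeline stage consumes:

* a **harmonic alchemy** toy — one particle in a harmonic well whose force
  constant is interpolated linearly from ``k0`` to ``k1`` over the coupling
  schedule.  Its partition function is known in closed form, so the exact
  endpoint free energy is ``(kT/2) ln(k1/k0)`` and every estimator can be
  validated against it;
* **Gaussian work pairs** — forward perturbation energies drawn from
  ``N(mu_f, sigma^2)`` with backward samples drawn Crooks-consistently from
  ``N(-mu_f + sigma^2/kT, sigma^2)``, implying the exact free energy
  ``mu_f - sigma^2/(2 kT)``.  The overlap of the pair is controlled by
  ``sigma``;
* **perturbation networks** — edges generated from known node free
  energies plus Gaussian noise, optionally with a decoy conformer candidate
  offset unfavourably, so network composition and conformer selection can
  be tested against planted truth.

``load_fixtures`` returns the study's printed data tables (docking scores
and experimental affinities; QM/MM energy components; perturbation edges
with conformer candidates) as DataFrames, verified against recorded
checksums.  Defaults mirror the study conditions: 100 samples per window
(1 ns sampled every 10 ps), 300 K, and the 13-point coupling schedule.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, LAMBDA_SCHEDULE, kt_kj_per_mol
from .estimators import ReducedPotentialSet, WindowSamples
from .exceptions import DataCorruptionError, InputError
from .network import (
    EdgeCandidate,
    Ligand,
    PerturbationEdge,
    PerturbationNetwork,
)

__all__ = [
    "HarmonicAlchemySpec",
    "HarmonicAlchemyResult",
    "GaussianWorkSpec",
    "SyntheticNetworkSpec",
    "SyntheticNetwork",
    "FixtureSet",
    "sample_harmonic_alchemy",
    "sample_gaussian_work",
    "generate_network",
    "load_fixtures",
    "set1_like_spec",
]

_CHECKSUMS = {
    "table3.csv": "8ddadf76450675954a3a1c7a8ae409df4dbfa4c7e774ef44a888ae7c290e06c9",
    "table5.csv": "8625a483234d3eb3fcb450b628e669865a65675ff51a3122ce3e78b6a411c40f",
    "table7.csv": "440b15c6cafeec3badaa9143ea9d82a5d7f3acf8f030317350314812b9b9a07c",
    "ligands.csv": "33e695a21453d4eb9a2a2ee3e8f78f5c1a01a13f57c63eae41a8c859d04e9ad8",
}


@dataclass(frozen=True)
class HarmonicAlchemySpec:
    """Linear interpolation of a harmonic force constant; exact dG known."""

    k0: float = 1.0
    k1: float = 4.0
    lambda_schedule: tuple = LAMBDA_SCHEDULE
    n_per_state: int = 100
    temperature: float = DEFAULT_TEMPERATURE
    seed: int | None = None

    def __post_init__(self):
        if self.k0 <= 0 or self.k1 <= 0:
            raise InputError("force constants must be positive")
        if self.n_per_state < 2:
            raise InputError("n_per_state must be >= 2")

    @property
    def exact_dg(self) -> float:
        """Closed-form endpoint free energy ``(kT/2) ln(k1/k0)`` (kJ/mol)."""
        return 0.5 * kt_kj_per_mol(self.temperature) * np.log(self.k1 / self.k0)

    def force_constant(self, lam: float) -> float:
        return self.k0 + lam * (self.k1 - self.k0)


@dataclass
class HarmonicAlchemyResult:
    """Generated potentials plus everything the four estimators need."""

    rps: ReducedPotentialSet
    exact_dg: float
    dudl: list[np.ndarray]  # per-state dU/dlambda samples (kJ/mol)
    spec: HarmonicAlchemySpec


def sample_harmonic_alchemy(spec: HarmonicAlchemySpec) -> HarmonicAlchemyResult:
    """Draw independent configurations per state and evaluate all states.

    Positions at state k follow ``N(0, kT/k(lambda_k))``; the potential of
    each snapshot is evaluated at every state (``U = k(lambda) x^2 / 2``),
    giving the full multistate matrix, adjacent-window perturbation
    energies, and analytic dU/dlambda samples
    ``(k1 - k0) x^2 / 2``.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    kt = kt_kj_per_mol(spec.temperature)
    lams = np.asarray(spec.lambda_schedule, dtype=float)
    ks = np.array([spec.force_constant(l) for l in lams])
    xs = []
    for k in ks:
        xs.append(rng.normal(0.0, np.sqrt(kt / k), size=spec.n_per_state))
    x_all = np.concatenate(xs)
    origin = np.repeat(np.arange(lams.size), spec.n_per_state)
    u = 0.5 * ks[:, None] * x_all[None, :] ** 2
    rps = ReducedPotentialSet(
        lambdas=lams, u=u, origin=origin, temperature=spec.temperature
    )
    dudl = [0.5 * (spec.k1 - spec.k0) * x**2 for x in xs]
    return HarmonicAlchemyResult(
        rps=rps, exact_dg=spec.exact_dg, dudl=dudl, spec=spec
    )


@dataclass(frozen=True)
class GaussianWorkSpec:
    """Crooks-consistent Gaussian forward/backward work distributions."""

    mu_f: float = 2.0
    sigma: float = 2.0
    n_f: int = 100
    n_r: int = 100
    temperature: float = DEFAULT_TEMPERATURE
    lambda_low: float = 0.0
    lambda_high: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise InputError("sigma must be positive")
        if self.n_f < 2 or self.n_r < 2:
            raise InputError("need at least 2 samples per direction")

    @property
    def implied_dg(self) -> float:
        """Exact free energy of the pair: ``mu_f - sigma^2/(2 kT)``."""
        return self.mu_f - self.sigma**2 / (2.0 * kt_kj_per_mol(self.temperature))

    @property
    def mu_r(self) -> float:
        """Mean of the reverse work distribution (Crooks-consistent)."""
        return -self.mu_f + self.sigma**2 / kt_kj_per_mol(self.temperature)


def sample_gaussian_work(spec: GaussianWorkSpec) -> tuple[WindowSamples, float]:
    """Draw a Crooks-consistent window; returns (samples, implied dG)."""
    rng = np.random.default_rng(spec.seed)
    fwd = rng.normal(spec.mu_f, spec.sigma, size=spec.n_f)
    bwd = rng.normal(spec.mu_r, spec.sigma, size=spec.n_r)
    window = WindowSamples(
        lambda_low=spec.lambda_low, lambda_high=spec.lambda_high,
        dU_forward=fwd, dU_backward=bwd,
    )
    return window, spec.implied_dg


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Perturbation network from known node free energies plus edge noise.

    ``conformer_offset`` plants a decoy candidate on every edge touching a
    reference node, displaced unfavourably for the perturbed ligand; zero
    disables candidate generation.
    """

    node_dgs: tuple  # ((id, dG or None for reference), ...)
    edges: tuple  # ((from_id, to_id), ...)
    reference_ids: frozenset = frozenset()
    noise_sd: float = 0.0
    edge_se: float = 0.5
    conformer_offset: float = 8.0
    set_id: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


@dataclass
class SyntheticNetwork:
    net: PerturbationNetwork
    truth: dict  # node id -> true dG (kJ/mol), references included
    spec: SyntheticNetworkSpec


def set1_like_spec(noise_sd: float = 0.0, seed: int | None = None,
                   conformer_offset: float = 8.0) -> SyntheticNetworkSpec:
    """A five-ligand star through one reference, like the first ligand set."""
    return SyntheticNetworkSpec(
        node_dgs=(
            ("A", -32.0), ("B", -38.0), ("C", -28.0), ("D", -27.5),
            ("E", -30.0), ("ref", -31.0),
        ),
        edges=(("ref", "A"), ("B", "C"), ("C", "ref"), ("D", "ref"),
               ("E", "ref")),
        reference_ids=frozenset({"ref"}),
        noise_sd=noise_sd,
        conformer_offset=conformer_offset,
        set_id=1,
        seed=seed,
    )


def generate_network(spec: SyntheticNetworkSpec) -> SyntheticNetwork:
    """Build a network whose edges are node differences plus Gaussian noise.

    Edge values follow the convention ``value = dG(to) - dG(from)``.  Edges
    touching a reference node additionally carry a decoy conformer whose
    value is offset so the planted candidate is always the favourable one.
    The graph must be connected.
    """
    rng = np.random.default_rng(spec.seed)
    truth = dict(spec.node_dgs)
    ligands = {}
    for lid, dg in spec.node_dgs:
        is_ref = lid in spec.reference_ids
        ligands[lid] = Ligand(
            id=lid, set_id=spec.set_id or 0,
            experimental_dg=None if is_ref else dg,
            is_reference=is_ref,
        )
    edges = []
    for a, b in spec.edges:
        if a not in truth or b not in truth:
            raise InputError(f"edge ({a},{b}) references unknown node")
        value = truth[b] - truth[a] + rng.normal(0.0, spec.noise_sd)
        cands = [EdgeCandidate(value=float(value), se=spec.edge_se,
                               conformer="conf1")]
        touches_ref = a in spec.reference_ids or b in spec.reference_ids
        if spec.conformer_offset > 0 and touches_ref:
            # Decoy displaced so the planted candidate stays favourable:
            # lower value for X->ref edges, higher for ref->X.
            sign = -1.0 if b in spec.reference_ids else 1.0
            cands.append(EdgeCandidate(
                value=float(value + sign * spec.conformer_offset),
                se=spec.edge_se, conformer="conf2",
            ))
        edges.append(PerturbationEdge(from_ligand=a, to_ligand=b,
                                      candidates=tuple(cands)))
    net = PerturbationNetwork(ligands=ligands, edges=edges, set_id=spec.set_id)
    if not nx.is_connected(net._graph):
        raise InputError("generated network is disconnected")
    return SyntheticNetwork(net=net, truth=truth, spec=spec)


@dataclass
class FixtureSet:
    """The study's printed tables, checksummed on load.

    ``table3``: docking/MM-GBSA scores and experimental absolute dG;
    ``table5``: QM/MM energy components (19 ligands, 12 numeric columns);
    ``table7``: perturbation edges with conformer candidates and, for the
    directly comparable second set, experimental relative affinities;
    ``ligands``: node table including the four reference ligands.
    """

    table3: pd.DataFrame
    table5: pd.DataFrame
    table7: pd.DataFrame
    ligands: pd.DataFrame
    lambda_schedule: tuple = LAMBDA_SCHEDULE

    def network(self, set_id: int, block: str = "fes") -> PerturbationNetwork:
        """Assemble the perturbation network for one ligand set/block."""
        lig_rows = self.ligands[self.ligands["set"] == set_id]
        ligands = {}
        for _, row in lig_rows.iterrows():
            exp = row["exp_dg"]
            ligands[row["id"]] = Ligand(
                id=row["id"], set_id=set_id,
                experimental_dg=None if pd.isna(exp) else float(exp),
                is_reference=bool(row["is_reference"]),
                non_binder=bool(row["non_binder"]),
            )
        sel = self.table7[
            (self.table7["set"] == set_id) & (self.table7["block"] == block)
        ]
        if sel.empty:
            raise InputError(f"no edges for set {set_id}, block {block!r}")
        edges = []
        for (a, b), grp in sel.groupby(["from", "to"], sort=False):
            cands = tuple(
                EdgeCandidate(value=float(r["value"]), se=float(r["se"]),
                              conformer=str(r["conformer"]))
                for _, r in grp.iterrows()
            )
            chosen = grp["selected"].astype(bool)
            selected = None
            if chosen.any():
                idx = int(np.nonzero(chosen.to_numpy())[0][0])
                selected = cands[idx]
            edges.append(PerturbationEdge(
                from_ligand=str(a), to_ligand=str(b),
                candidates=cands, selected=selected,
            ))
        return PerturbationNetwork(ligands=ligands, edges=edges, set_id=set_id)

    def set2_pairs(self, block: str):
        """Calculated vs experimental relative affinities for one second-set
        block, as aligned arrays (labels, calc, se, exp)."""
        sel = self.table7[
            (self.table7["set"] == 2) & (self.table7["block"] == block)
        ]
        if sel.empty:
            raise InputError(f"unknown set-2 block {block!r}")
        labels = [f"{r['from']}->{r['to']}" for _, r in sel.iterrows()]
        return (
            labels,
            sel["value"].to_numpy(dtype=float),
            sel["se"].to_numpy(dtype=float),
            sel["exp"].to_numpy(dtype=float),
        )


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("fepbench.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise DataCorruptionError(
            f"fixture {name} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    for col in ("ligand", "id", "from", "to", "conformer", "block", "structure"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def load_fixtures() -> FixtureSet:
    """Load and verify the packaged study tables."""
    return FixtureSet(
        table3=_read_checked("table3.csv"),
        table5=_read_checked("table5.csv"),
        table7=_read_checked("table7.csv"),
        ligands=_read_checked("ligands.csv"),
    )
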