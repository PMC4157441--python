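"""Deformable elastic network (DEN) restraints.

A DEN is a sparse set of harmonic distance restraints between randomly chosen
atom pairs.  Each restraint carries a current equilibrium distance d0 that is
*deformed* once per temperature-decrement step of slow-cooling annealing:

    d0 ← d0 + κ·[ γ·(d(t) − d0) + (1−γ)·(d_ref − d0) ]

where d(t) is the current model distance and d_ref the distance in the
reference model.  γ=0 pins the equilibria to the reference model; γ=1 lets
them track the refining model (the reference distances are then never used,
and the network retains only a slowly dissipating memory of the starting
model).  κ sets the update speed; 0.1 is the customary default.

The restraint energy is  E_DEN = w_DEN · Σ_ij (d_ij − d0_ij)²  with the
spring constant absorbed into the weight w_DEN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structures import Structure


class SelectionError(RuntimeError):
    """No eligible restraint pairs under the given selection criteria."""


class CorrespondenceError(ValueError):
    """Starting and reference structures do not share atom correspondence."""


@dataclass(frozen=True)
class SelectionConfig:
    """Eligibility rules for random restraint-pair selection.

    Pairs are eligible when their *reference-model* distance lies in
    [d_lo, d_hi], their sequence separation |Δresidue| lies in
    [seq_sep_lo, seq_sep_hi] (same-chain pairs only), and — unless
    allow_inter_chain — both atoms share one chain.  seq_sep_hi=None lifts the
    separation limit (the very-low-resolution multi-chain mode, where
    inter-chain pairs are also desired).
    """

    d_lo: float = 3.0
    d_hi: float = 15.0
    seq_sep_lo: int = 0
    seq_sep_hi: int | None = 10
    allow_inter_chain: bool = False
    n_restraints: int | str = "auto"   # "auto" → one per selected atom
    include_hydrogens: bool = False

    def __post_init__(self):
        if not (0 < self.d_lo < self.d_hi):
            raise ValueError("require 0 < d_lo < d_hi")
        if self.seq_sep_lo < 0:
            raise ValueError("seq_sep_lo must be >= 0")
        if self.seq_sep_hi is not None and self.seq_sep_hi < self.seq_sep_lo:
            raise ValueError("require seq_sep_lo <= seq_sep_hi")


@dataclass
class DENNetwork:
    """Fixed list of restrained pairs; only the equilibria d0 evolve."""

    pairs: np.ndarray        # (N, 2) int atom indices, i < j
    d0: np.ndarray           # (N,) current equilibrium distances, Å
    d_ref: np.ndarray        # (N,) reference-model distances, Å
    selection_seed: int
    config: SelectionConfig

    def __len__(self) -> int:
        return len(self.pairs)

    def copy(self) -> "DENNetwork":
        return DENNetwork(
            self.pairs.copy(), self.d0.copy(), self.d_ref.copy(),
            self.selection_seed, self.config,
        )

    def to_tsv(self, structure: Structure, path) -> None:
        """Serialize the restraint list for inspection and replay."""
        with open(path, "w") as fh:
            fh.write("chain_i\tresi_i\tatom_i\tchain_j\tresi_j\tatom_j\td0\td_ref\n")
            for (i, j), d0, dref in zip(self.pairs, self.d0, self.d_ref):
                ai, aj = structure.atoms[i], structure.atoms[j]
                fh.write(
                    f"{ai.chain_id}\t{ai.residue_index}\t{ai.name}\t"
                    f"{aj.chain_id}\t{aj.residue_index}\t{aj.name}\t"
                    f"{d0:.17g}\t{dref:.17g}\n"
                )


def check_correspondence(a: Structure, b: Structure) -> None:
    if len(a) != len(b):
        raise CorrespondenceError(
            f"atom count mismatch: {len(a)} vs {len(b)}"
        )
    for k, (x, y) in enumerate(zip(a.atoms, b.atoms)):
        if (x.name, x.chain_id) != (y.name, y.chain_id):
            raise CorrespondenceError(f"atom {k} differs: {x.name}/{x.chain_id} vs {y.name}/{y.chain_id}")


def eligible_pairs(
    reference: Structure,
    config: SelectionConfig,
    atom_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Enumerate all atom pairs eligible under ``config`` on the reference model.

    Returns an (M, 2) array of index pairs i<j, in deterministic lexicographic
    order.  ``atom_mask`` restricts selection to a subset of atoms (partial
    reference models).
    """
    xyz = reference.coords
    n = len(reference)
    elements = np.array(reference.elements)
    resi = np.array([a.residue_index for a in reference.atoms])
    chain = np.array([a.chain_id for a in reference.atoms])

    keep = np.ones(n, dtype=bool)
    if not config.include_hydrogens:
        keep &= elements != "H"
    if atom_mask is not None:
        keep &= np.asarray(atom_mask, dtype=bool)
    idx = np.flatnonzero(keep)
    if len(idx) < 2:
        raise SelectionError("fewer than two selectable atoms")

    sub = xyz[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    lo2, hi2 = config.d_lo**2, config.d_hi**2
    ii, jj = np.triu_indices(len(idx), k=1)
    ok = (d2[ii, jj] >= lo2) & (d2[ii, jj] <= hi2)

    ci, cj = chain[idx[ii]], chain[idx[jj]]
    same_chain = ci == cj
    sep = np.abs(resi[idx[ii]] - resi[idx[jj]])
    seq_ok = sep >= config.seq_sep_lo
    if config.seq_sep_hi is not None:
        seq_ok &= sep <= config.seq_sep_hi
    # sequence separation is defined only within a chain; inter-chain pairs
    # bypass the test but are only allowed when configured
    ok &= np.where(same_chain, seq_ok, config.allow_inter_chain)

    pairs = np.column_stack([idx[ii[ok]], idx[jj[ok]]])
    return pairs


def select_restraints(
    structure: Structure,
    reference: Structure,
    config: SelectionConfig = SelectionConfig(),
    seed: int = 0,
    atom_mask: np.ndarray | None = None,
) -> DENNetwork:
    """Randomly select DEN restraint pairs.

    Eligibility (the distance window) is evaluated on the *reference* model;
    the initial equilibria d0 are set from *starting*-model distances so the
    model begins at the minimum of E_DEN.  Selection is a uniform sample
    without replacement (seeded shuffle of the enumerated eligible list) of
    size min(n_restraints, #eligible); n_restraints="auto" means one
    restraint per selectable atom.
    """
    check_correspondence(structure, reference)
    pairs = eligible_pairs(reference, config, atom_mask)
    if len(pairs) == 0:
        raise SelectionError("no eligible restraint pairs under the configuration")

    if config.n_restraints == "auto":
        elements = np.array(reference.elements)
        n_sel = int(np.sum(elements != "H")) if not config.include_hydrogens else len(reference)
        if atom_mask is not None:
            n_sel = int(np.sum(np.asarray(atom_mask, dtype=bool)))
    else:
        n_sel = int(config.n_restraints)
    n_sel = min(n_sel, len(pairs))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))[:n_sel]
    order.sort()  # stable order for reproducible downstream iteration
    chosen = pairs[order]

    xyz_start = structure.coords
    xyz_ref = reference.coords
    d0 = np.linalg.norm(xyz_start[chosen[:, 0]] - xyz_start[chosen[:, 1]], axis=1)
    d_ref = np.linalg.norm(xyz_ref[chosen[:, 0]] - xyz_ref[chosen[:, 1]], axis=1)
    return DENNetwork(chosen, d0, d_ref, int(seed), config)


def den_energy_forces(
    positions: np.ndarray, network: DENNetwork, w_den: float
) -> tuple[float, np.ndarray]:
    """E_DEN = w_DEN Σ (d_ij − d0_ij)² and its negative gradient."""
    positions = np.asarray(positions, dtype=float)
    forces = np.zeros_like(positions)
    if len(network) == 0 or w_den == 0.0:
        return 0.0, forces
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    dvec = positions[i] - positions[j]
    d = np.linalg.norm(dvec, axis=1)
    if np.any(d < 1e-8):
        raise FloatingPointError("coincident restrained atoms (zero distance)")
    delta = d - network.d0
    energy = w_den * float(np.sum(delta**2))
    # dE/dr_i = 2 w (d − d0) · (r_i − r_j)/d
    g = (2.0 * w_den * delta / d)[:, None] * dvec
    np.add.at(forces, i, -g)
    np.add.at(forces, j, g)
    return energy, forces


def update_equilibrium(
    network: DENNetwork, positions: np.ndarray, gamma: float, kappa: float
) -> DENNetwork:
    """One deformation step of the restraint equilibria (applied per
    temperature decrement during slow cooling).  Returns a new network;
    the pair list itself never changes."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if not (0.0 < kappa <= 1.0):
        raise ValueError("kappa must lie in (0, 1]")
    positions = np.asarray(positions, dtype=float)
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    d0 = network.d0 + kappa * (
        gamma * (d - network.d0) + (1.0 - gamma) * (network.d_ref - network.d0)
    )
    out = network.copy()
    out.d0 = d0
    return out
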