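"""Seed-deterministic synthetic structure ensembles.

Real inputs to this pipeline are hundreds of AF2 models or MD snapshots —
far beyond desk scale.  These generators emulate the *statistical* structure
of such ensembles with minimal geometry:

* a Cα trace as a self-avoiding walk (fixed 3.8 Å virtual bond, hard
  excluded volume via rejection sampling), with an optional harmonic bias
  toward a target radius of gyration;
* one "sidechain-proxy" heavy atom per residue at a fixed 1.5 Å offset, the
  minimal addition that makes the shortest-heavy-atom residue distance
  distinct from the Cα distance;
* *ordered* ensembles = one reference plus i.i.d. Gaussian coordinate noise
  and a random rigid motion per member (tight, sub-Å heterogeneity at small
  sigma — the well-folded archetype);
* *disordered* ensembles = independent self-avoiding walks sharing only the
  residue layout (multi-Å pairwise RMSD, mostly unrepeated contacts — the
  IDP archetype);
* *planted-persistency* ensembles where chosen residue pairs are in contact
  in exactly round(f·N) members, for exact recovery tests;
* C2-symmetric closed-loop homodimer ensembles;
* pLDDT-like confidence tracks with controllable across-model variance.

No physical realism is claimed (no Ramachandran statistics, no sidechain
rotamers); only the ensemble-level signals the analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .structure_io import Atom, StructureEnsemble, StructureModel, write_pdb

__all__ = [
    "GeneratorConfig",
    "ChainGrowthError",
    "make_reference_chain",
    "ordered_ensemble",
    "disordered_ensemble",
    "planted_persistency_ensemble",
    "synthetic_dimer_ensemble",
    "synthetic_confidence",
    "generate",
    "write_ensemble",
]

BOND_LENGTH = 3.8          # Å, consecutive Cα virtual bond
EXCLUDED_RADIUS = 2.0      # Å, hard-sphere radius of a Cα bead
PROXY_OFFSET = 1.5         # Å, sidechain-proxy displacement from the Cα

_AA20 = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
         "THR TRP TYR VAL").split()


class ChainGrowthError(RuntimeError):
    """Self-avoiding-walk growth exhausted its rejection budget."""


@dataclass
class GeneratorConfig:
    """Declarative description of one synthetic ensemble."""

    mode: str = "ordered"  # ordered | disordered | planted | dimer
    n_residues: int = 100
    n_members: int = 20
    seed: int = 0
    perturbation_sigma: float = 0.2   # Å, ordered-mode coordinate noise
    compactness: float = 0.5          # reference-chain R_gyr bias strength
    bond_length: float = BOND_LENGTH
    excluded_volume_radius: float = EXCLUDED_RADIUS
    planted_contacts: list[tuple[int, int, float]] = field(default_factory=list)
    plddt_base: float | None = None   # constant base track if set
    plddt_noise: float = 0.0
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.perturbation_sigma < 0:
            raise ValueError("perturbation_sigma must be >= 0")
        for i, j, f in self.planted_contacts:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"planted frequency {f} outside [0, 1]")
        if self.mode not in ("ordered", "disordered", "planted", "dimer"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# chain construction helpers

def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9 * np.linalg.norm(v):
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _proxy_positions(ca: np.ndarray, pair_contacts: bool = True
                     ) -> np.ndarray:
    """Sidechain-proxy atom per residue, PROXY_OFFSET Å off the backbone.

    With ``pair_contacts`` (the default), residues whose Cαs are spatial
    neighbors (non-adjacent in sequence, 4.8–6.3 Å apart) are greedily
    matched and their proxies point at each other, landing 1.8–3.3 Å apart
    — solid contacts well inside the 3.5 Å cutoff, emulating packed
    sidechains in a folded core.  Unmatched residues get the normal of the
    local backbone turn (arbitrary perpendicular for straight segments and
    chain ends).  Fully deterministic given the Cα trace.
    """
    n = len(ca)
    proxies = np.empty_like(ca)
    paired: dict[int, int] = {}
    if pair_contacts and n > 3:
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(ca))
        cand = [(d[i, j], i, j) for i in range(n) for j in range(i + 2, n)
                if 4.8 <= d[i, j] <= 6.3]
        for _, i, j in sorted(cand):
            if i not in paired and j not in paired:
                paired[i] = j
                paired[j] = i
    for k in range(n):
        if k in paired:
            u = ca[paired[k]] - ca[k]
            proxies[k] = ca[k] + PROXY_OFFSET * u / np.linalg.norm(u)
            continue
        v_in = ca[k] - ca[k - 1] if k > 0 else ca[k + 1] - ca[k]
        v_out = ca[k + 1] - ca[k] if k < n - 1 else ca[k] - ca[k - 1]
        normal = np.cross(v_in, v_out)
        norm = np.linalg.norm(normal)
        if norm < 1e-8:
            direction = _any_perpendicular(v_out)
        else:
            direction = normal / norm
        proxies[k] = ca[k] + PROXY_OFFSET * direction
    return proxies


def _grow_saw(n_residues: int, rng: np.random.Generator,
              bond_length: float = BOND_LENGTH,
              excluded_radius: float = EXCLUDED_RADIUS,
              compactness: float = 0.0,
              target_rgyr: float | None = None,
              tries_per_step: int = 300, restarts: int = 60) -> np.ndarray:
    """Grow a self-avoiding Cα walk by rejection sampling.

    Non-consecutive beads must stay at least ``2 * excluded_radius`` apart.
    With ``compactness`` > 0 a candidate step whose provisional radius of
    gyration exceeds the target is accepted with probability
    exp(-compactness * (R_gyr - target)^2) — a one-sided harmonic penalty
    that biases the walk toward compact conformations without ever violating
    excluded volume.
    """
    min_sep = 2.0 * excluded_radius
    if target_rgyr is None:
        # Scaling of a collapsed globule of hard beads: r0 * n^(1/3).
        target_rgyr = 2.5 * n_residues ** (1.0 / 3.0)
    for restart in range(restarts):
        # growth into a dead end is common at high compactness; relax the
        # target a little on every restart so long chains still terminate
        eff_target = target_rgyr * (1.0 + 0.05 * restart)
        coords = np.zeros((n_residues, 3))
        ok = True
        for k in range(1, n_residues):
            placed = False
            for _ in range(tries_per_step):
                step = _random_unit(rng)[0] * bond_length
                cand = coords[k - 1] + step
                if k > 1:
                    dists = np.linalg.norm(coords[:k - 1] - cand, axis=1)
                    if np.min(dists) < min_sep:
                        continue
                if compactness > 0:
                    pts = coords[:k + 1].copy()
                    pts[k] = cand
                    centred = pts - pts.mean(axis=0)
                    rg = np.sqrt(np.mean(np.sum(centred ** 2, axis=1)))
                    excess = max(0.0, rg - eff_target)
                    if excess > 0 and rng.random() >= np.exp(
                            -compactness * excess ** 2):
                        continue
                coords[k] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise ChainGrowthError(
        f"could not grow a {n_residues}-residue self-avoiding walk; "
        "lower the compactness bias")


def _default_sequence(n_residues: int, seed: int) -> list[str]:
    # Sub-seeded so the sequence is stable while coordinates consume `seed`.
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 97]))
    return [_AA20[i] for i in rng.integers(len(_AA20), size=n_residues)]


def _build_model(model_id: str, ca: np.ndarray, proxies: np.ndarray,
                 resnames: list[str], chain_id: str = "A",
                 start_index: int = 1,
                 confidence: float | np.ndarray = 90.0) -> StructureModel:
    conf = np.broadcast_to(np.asarray(confidence, dtype=float), (len(ca),))
    atoms: list[Atom] = []
    for k in range(len(ca)):
        common = dict(chain_id=chain_id, residue_index=start_index + k,
                      insertion_code="", residue_name=resnames[k],
                      confidence=float(conf[k]))
        atoms.append(Atom(atom_name="CA", element="C",
                          position=tuple(ca[k]), **common))
        atoms.append(Atom(atom_name="CB", element="C",
                          position=tuple(proxies[k]), **common))
    return StructureModel(model_id, atoms)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans


# ---------------------------------------------------------------------------
# public generators

def make_reference_chain(n_residues: int, compactness: float = 0.5,
                         seed: int = 0,
                         bond_length: float = BOND_LENGTH,
                         excluded_volume_radius: float = EXCLUDED_RADIUS,
                         sequence: list[str] | None = None,
                         model_id: str = "reference") -> StructureModel:
    """One self-avoiding Cα+proxy chain, seed-deterministic."""
    rng = np.random.default_rng(seed)
    ca = _grow_saw(n_residues, rng, bond_length=bond_length,
                   excluded_radius=excluded_volume_radius,
                   compactness=compactness)
    resnames = sequence or _default_sequence(n_residues, seed)
    return _build_model(model_id, ca, _proxy_positions(ca), resnames)


def ordered_ensemble(reference: StructureModel, sigma: float,
                     n_members: int, seed: int = 0,
                     rigid_motions: bool = True,
                     source_tag: str = "synthetic-ordered"
                     ) -> StructureEnsemble:
    """Reference + i.i.d. Gaussian noise (+ random rigid motion) per member.

    Emulates the tight ensembles of a well-folded protein: pairwise RMSD
    grows linearly with ``sigma`` and stays sub-Å for sigma around 0.2 Å.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    members = []
    for k in range(n_members):
        coords = reference.coords + rng.normal(0.0, sigma,
                                               size=reference.coords.shape)
        if rigid_motions:
            rot, trans = _random_rigid(rng)
            coords = coords @ rot.T + trans
        members.append(reference.with_coords(coords, model_id=f"model_{k:03d}"))
    return StructureEnsemble(members, source_tag=source_tag)


def disordered_ensemble(n_residues: int, n_members: int, seed: int = 0,
                        compactness: float = 0.0,
                        source_tag: str = "synthetic-disordered"
                        ) -> StructureEnsemble:
    """Independent self-avoiding walks sharing one residue layout.

    Each member is a fresh walk: contacts rarely repeat between members and
    pairwise RMSDs sit at several Å for chains of ~100 residues — the IDP
    archetype.
    """
    resnames = _default_sequence(n_residues, seed)
    rng = np.random.default_rng(seed)
    members = []
    for k in range(n_members):
        ca = _grow_saw(n_residues, rng, compactness=compactness)
        members.append(_build_model(f"model_{k:03d}", ca,
                                    _proxy_positions(ca), resnames))
    return StructureEnsemble(members, source_tag=source_tag)


def _extended_backbone(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Contact-free zigzag: Cα along x, proxies alternating in z.

    Nearest heavy-atom distance between any two residues is > 4 Å, so the
    base conformation has no contacts at the 3.5 Å cutoff at all — planted
    contacts are then the only ones present.
    """
    ca = np.zeros((n_residues, 3))
    ca[:, 0] = BOND_LENGTH * np.arange(n_residues)
    proxies = ca.copy()
    proxies[:, 2] = PROXY_OFFSET * np.where(np.arange(n_residues) % 2, -1, 1)
    return ca, proxies


def planted_persistency_ensemble(planted_contacts, n_members: int,
                                 seed: int = 0,
                                 n_residues: int | None = None,
                                 rigid_motions: bool = False,
                                 source_tag: str = "synthetic-planted",
                                 _retry_budget: int = 10
                                 ) -> StructureEnsemble:
    """Ensemble whose contacts occur at exactly the planted frequencies.

    ``planted_contacts`` is a list of ``(i, j, f)`` with 0-based residue
    positions (non-adjacent, each residue used once) and target frequency f.
    The contact is realized by parking the two sidechain proxies 3.0 Å apart
    on a rail well off the backbone in exactly ``round(f * n_members)``
    members (ties-to-even), and leaving them > 6 Å apart in the rest; the
    resulting edge weight — and hence the persistency class — is exact, not
    stochastic.  A post-construction audit verifies that no unplanned
    contact was created.
    """
    planted = [(int(i), int(j), float(f)) for i, j, f in planted_contacts]
    if not planted:
        raise ValueError("at least one planted contact is required")
    used: set[int] = set()
    for i, j, f in planted:
        if abs(i - j) < 2:
            raise ValueError(f"planted pair ({i}, {j}) is sequence-adjacent")
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"planted frequency {f} outside [0, 1]")
        if i in used or j in used:
            raise ValueError("each residue may appear in one planted pair")
        used.update((i, j))
    if n_residues is None:
        n_residues = max(used) + 3
    if max(used) >= n_residues:
        raise ValueError("planted residue index outside the chain")

    resnames = _default_sequence(n_residues, seed)
    rng = np.random.default_rng(seed)
    ca, base_proxies = _extended_backbone(n_residues)

    # Which members carry each planted contact (exact counts).
    membership: list[np.ndarray] = []
    for _, _, f in planted:
        k = round(f * n_members)
        chosen = np.zeros(n_members, dtype=bool)
        chosen[rng.choice(n_members, size=k, replace=False)] = True
        membership.append(chosen)

    from .contact_networks import contact_map, residue_distance_map

    for attempt in range(_retry_budget):
        rail_y = 5.0 + 2.0 * attempt
        members = []
        ok = True
        for m in range(n_members):
            proxies = base_proxies.copy()
            for p, (i, j, _) in enumerate(planted):
                if membership[p][m]:
                    cx = 0.5 * (ca[i, 0] + ca[j, 0])
                    y = rail_y + 8.0 * p  # one rail per pair, 8 Å apart
                    proxies[i] = (cx - 1.5, y, 0.0)
                    proxies[j] = (cx + 1.5, y, 0.0)
            model = _build_model(f"model_{m:03d}", ca, proxies, resnames)
            if rigid_motions:
                rot, trans = _random_rigid(rng)
                model = model.transformed(rot, trans,
                                          model_id=model.model_id)
            members.append(model)
        # audit: contacts must be exactly the planted "on" pairs
        for m, model in enumerate(members):
            expected = {tuple(sorted((i, j)))
                        for p, (i, j, _) in enumerate(planted)
                        if membership[p][m]}
            cmap = contact_map(residue_distance_map(model)).matrix
            got = {tuple(sorted((a, b)))
                   for a, b in zip(*np.nonzero(np.triu(cmap, k=1)))}
            if got != expected:
                ok = False
                break
        if ok:
            return StructureEnsemble(members, source_tag=source_tag)
    raise ChainGrowthError(
        "could not realize the planted contacts without side effects")


def synthetic_dimer_ensemble(n_residues_per_chain: int = 60,
                             n_members: int = 10, seed: int = 0,
                             noise_sigma: float = 0.5,
                             separation: float = 6.0,
                             rigid_motions: bool = True,
                             planted_interchain=None,
                             source_tag: str = "synthetic-dimer"
                             ) -> StructureEnsemble:
    """C2-symmetric closed-loop homodimer ensemble.

    Each chain is a ring (circumference = n · bond length) with outward
    proxies; chain B is chain A rotated 180° about the x axis, the two rings
    stacked ``separation`` Å apart.  Per-member Gaussian noise of
    ``noise_sigma`` makes the ensemble tight but not degenerate, so the
    chain-swap RMSD agrees with the identity RMSD up to that noise.

    ``planted_interchain`` optionally lists ``(i, j, f)`` pairs (0-based
    positions within each chain) realized as A-B proxy contacts in
    round(f·N) members.
    """
    n = n_residues_per_chain
    rng = np.random.default_rng(seed)
    radius = n * BOND_LENGTH / (2.0 * np.pi)
    theta = 2.0 * np.pi * np.arange(n) / n
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                     np.zeros(n)], axis=1)
    outward = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    ca_a = ring + np.array([0.0, 0.0, +0.5 * separation])
    px_a = ca_a + PROXY_OFFSET * outward
    flip = np.diag([1.0, -1.0, -1.0])  # C2 about the x axis
    ca_b = ca_a @ flip.T
    px_b = px_a @ flip.T
    resnames = _default_sequence(n, seed)

    planted = [(int(i), int(j), float(f)) for i, j, f in
               (planted_interchain or [])]
    membership = []
    for _, _, f in planted:
        chosen = np.zeros(n_members, dtype=bool)
        chosen[rng.choice(n_members, size=round(f * n_members),
                          replace=False)] = True
        membership.append(chosen)

    members = []
    for m in range(n_members):
        pa, pb = px_a.copy(), px_b.copy()
        for p, (i, j, _) in enumerate(planted):
            if membership[p][m]:
                mid = 0.5 * (ca_a[i] + ca_b[j])
                u = ca_b[j] - ca_a[i]
                u = u / np.linalg.norm(u)
                pa[i] = mid - 1.5 * u
                pb[j] = mid + 1.5 * u
        coords_a = np.empty((2 * n, 3))
        coords_a[0::2], coords_a[1::2] = ca_a, pa
        coords_b = np.empty((2 * n, 3))
        coords_b[0::2], coords_b[1::2] = ca_b, pb
        coords = np.vstack([coords_a, coords_b])
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
        if rigid_motions:
            rot, trans = _random_rigid(rng)
            coords = coords @ rot.T + trans
        atoms: list[Atom] = []
        for chain_id, offset in (("A", 0), ("B", 2 * n)):
            for k in range(n):
                common = dict(chain_id=chain_id, residue_index=k + 1,
                              insertion_code="", residue_name=resnames[k],
                              confidence=90.0)
                atoms.append(Atom(atom_name="CA", element="C",
                                  position=tuple(coords[offset + 2 * k]),
                                  **common))
                atoms.append(Atom(atom_name="CB", element="C",
                                  position=tuple(coords[offset + 2 * k + 1]),
                                  **common))
        members.append(StructureModel(f"model_{m:03d}", atoms))
    return StructureEnsemble(members, source_tag=source_tag)


def synthetic_confidence(ensemble: StructureEnsemble,
                         plddt_base_track: np.ndarray | float,
                         noise: float, seed: int = 0) -> StructureEnsemble:
    """Fill per-residue pLDDT-like confidences: clip(base + N(0, noise)).

    The base track (scalar or per-residue array in [0, 100]) is shared by
    all members; independent Gaussian noise of the given sd is added per
    member and residue, then clipped to [0, 100].  Values are constant
    across the atoms of a residue, as AF2 writes them.
    """
    n_res = ensemble.n_residues
    base = np.broadcast_to(np.asarray(plddt_base_track, dtype=float),
                           (n_res,))
    if np.any((base < 0) | (base > 100)):
        raise ValueError("base pLDDT track must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    members = []
    for model in ensemble:
        per_res = np.clip(base + rng.normal(0.0, noise, size=n_res),
                          0.0, 100.0)
        members.append(model.with_confidences(per_res[model.atom_residue]))
    return StructureEnsemble(members, source_tag=ensemble.source_tag)


# ---------------------------------------------------------------------------
# config-driven entry point and fixture export

def generate(config: GeneratorConfig) -> StructureEnsemble:
    """Build the ensemble a :class:`GeneratorConfig` describes."""
    if config.mode == "ordered":
        ref = make_reference_chain(config.n_residues,
                                   compactness=config.compactness,
                                   seed=config.seed,
                                   bond_length=config.bond_length,
                                   excluded_volume_radius=config.excluded_volume_radius)
        ens = ordered_ensemble(ref, config.perturbation_sigma,
                               config.n_members, seed=config.seed,
                               source_tag=config.source_tag or "synthetic-ordered")
    elif config.mode == "disordered":
        ens = disordered_ensemble(config.n_residues, config.n_members,
                                  seed=config.seed,
                                  source_tag=config.source_tag or "synthetic-disordered")
    elif config.mode == "planted":
        ens = planted_persistency_ensemble(config.planted_contacts,
                                           config.n_members,
                                           seed=config.seed,
                                           n_residues=config.n_residues,
                                           source_tag=config.source_tag or "synthetic-planted")
    else:  # dimer
        ens = synthetic_dimer_ensemble(config.n_residues, config.n_members,
                                       seed=config.seed,
                                       source_tag=config.source_tag or "synthetic-dimer")
    if config.plddt_base is not None:
        ens = synthetic_confidence(ens, config.plddt_base,
                                   config.plddt_noise, seed=config.seed)
    return ens


def write_ensemble(ensemble: StructureEnsemble, outdir,
                   config: GeneratorConfig | None = None,
                   multi_model: bool = False) -> dict:
    """Write ensemble members as PDB files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    if multi_model:
        path = outdir / "ensemble.pdb"
        write_pdb(ensemble, path)
        files.append(path.name)
    else:
        for model in ensemble:
            path = outdir / f"{model.model_id}.pdb"
            write_pdb(model, path)
            files.append(path.name)
    manifest = {
        "source_tag": ensemble.source_tag,
        "n_members": len(ensemble),
        "n_residues": ensemble.n_residues,
        "files": files,
        "config": asdict(config) if config is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2)
                                          + "\n")
    return manifest
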