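"""Interaction-fingerprint state decomposition and reweighted populations.

Frames are labelled by a small discrete fingerprint — which landscape region
the ligand occupies (pocket / vestibule intermediates / unbound), whether the
key pharmacophore contact is formed (CV below a contact threshold, the
salt-bridge analogue), and a tether-extension bin.  Microstates are the
distinct fingerprint combinations with reweighted probability above a floor;
rarer combinations are merged into their Hamming-nearest retained
microstate.  Because microstates come from discrete fingerprints rather than
geometric clustering, the decomposition is deterministic and invariant to
frame order.

Macrostates group microstates by the region feature into pocket /
intermediate / outside — the analogue of grouping ligand poses into
in-pocket, vestibule and external clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import stream
from .metad import EmptySelectionError, WeightedFrames
from .toy_systems import InvalidParameterError, PotentialSurface


def _macro_name(region_name: str) -> str:
    if region_name.startswith("intermediate"):
        return "intermediate"
    return region_name


def featurize(
    cv: np.ndarray,
    surface: PotentialSurface,
    *,
    contact_threshold: float = 2.0,
    extension_bin_width: float = 1.25,
    anchor: float | None = None,
) -> tuple[np.ndarray, list]:
    """Per-frame fingerprints: (region, key_contact, extension bin).

    ``key_contact`` is true where the CV is below ``contact_threshold`` (the
    in-pocket salt-bridge analogue); the extension bin is |cv - anchor|
    binned at ``extension_bin_width`` (the tether-extension analogue).
    Returns (n_frames, 3) integer fingerprints and the feature definition.
    """
    cv = np.asarray(cv, dtype=float)
    if anchor is None:
        anchor = float(surface.meta.get("anchor", [surface.domain[0, 0]])[0])
    region = surface.region_of(cv)
    region = np.where(region < 0, 0, region)
    contact = (cv < contact_threshold).astype(int)
    ext_bin = np.floor(np.abs(cv - anchor) / extension_bin_width).astype(int)
    fingerprints = np.column_stack([region, contact, ext_bin])
    definition = [
        ("region", "index of the CV-interval region (pocket / vestibule / unbound)"),
        ("key_contact", f"cv < {contact_threshold} (pharmacophore contact analogue)"),
        ("ext_bin", f"floor(|cv - {anchor}| / {extension_bin_width}) (tether extension bin)"),
    ]
    return fingerprints, definition


@dataclass
class StateDecomposition:
    """Frame microstate labels plus microstate -> macrostate mapping."""

    microstate_label: np.ndarray  # per input frame
    n_microstates: int
    fingerprints: np.ndarray  # (n_microstates, n_features), lexicographically sorted
    macrostate_of: list  # per microstate: "pocket" | "intermediate" | "outside" | ...
    fingerprint_definition: list = field(default_factory=list)

    def microstates_of_macro(self, macro: str) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.macrostate_of) if m == macro], dtype=int)

    @property
    def macrostates(self) -> list:
        seen = []
        for m in self.macrostate_of:
            if m not in seen:
                seen.append(m)
        return sorted(seen)

    def assign(self, fingerprints: np.ndarray) -> np.ndarray:
        """Label arbitrary frames; unseen fingerprints go to the
        Hamming-nearest microstate (ties to the lower index)."""
        fp = np.atleast_2d(fingerprints)
        # dedupe first: frames vastly outnumber distinct fingerprints
        uniq, inverse = np.unique(fp, axis=0, return_inverse=True)
        d = (uniq[:, None, :] != self.fingerprints[None, :, :]).sum(axis=2)
        return np.argmin(d, axis=1)[inverse]


def cluster_states(
    fingerprints: np.ndarray,
    weights: WeightedFrames | np.ndarray,
    *,
    region_names: list,
    floor: float = 1e-5,
    fingerprint_definition: list | None = None,
) -> StateDecomposition:
    """Microstates = distinct fingerprints above a probability floor.

    Combinations with total reweighted probability below ``floor`` are
    merged into their Hamming-nearest retained combination (ties broken
    toward the lower index in lexicographic order).  The macrostate of each
    microstate derives from its region feature.
    """
    fp = np.atleast_2d(np.asarray(fingerprints, dtype=int))
    if fp.shape[0] == 0:
        raise EmptySelectionError("no frames to cluster")
    w = weights.weights if isinstance(weights, WeightedFrames) else np.asarray(weights, float)
    if w.shape[0] != fp.shape[0]:
        raise InvalidParameterError("fingerprints and weights are not aligned")
    w = w / w.sum()

    uniq, inverse = np.unique(fp, axis=0, return_inverse=True)  # lexicographic order
    mass = np.bincount(inverse, weights=w, minlength=uniq.shape[0])
    retained = np.where(mass >= floor)[0]
    if retained.size == 0:
        retained = np.array([int(np.argmax(mass))])
    # map every unique combination to a retained microstate
    to_micro = np.empty(uniq.shape[0], dtype=int)
    for u in range(uniq.shape[0]):
        if mass[u] >= floor and u in retained:
            to_micro[u] = np.searchsorted(retained, u)
        else:
            d = (uniq[u][None, :] != uniq[retained]).sum(axis=1)
            to_micro[u] = int(np.argmin(d))  # argmin takes the lowest index on ties
    labels = to_micro[inverse]
    micro_fp = uniq[retained]
    macro = [_macro_name(region_names[r]) for r in micro_fp[:, 0]]
    return StateDecomposition(
        microstate_label=labels,
        n_microstates=retained.size,
        fingerprints=micro_fp,
        macrostate_of=macro,
        fingerprint_definition=fingerprint_definition or [],
    )


@dataclass
class StatePopulations:
    """Stationary microstate probabilities and macrostate free-energy gaps."""

    pi: np.ndarray
    group_probability: dict
    delta_F_groups: dict  # (A, B) -> (value_kT, bootstrap_sd)
    kT: float = 1.0


def _group_probs(decomposition, labels, w) -> tuple[np.ndarray, dict]:
    pi = np.bincount(labels, weights=w, minlength=decomposition.n_microstates)
    pi = pi / pi.sum()
    groups = {}
    for m in decomposition.macrostates:
        groups[m] = float(pi[decomposition.microstates_of_macro(m)].sum())
    return pi, groups


def _block_resample_indices(traj_index, frame_index, block_frames, rng):
    """Circular block bootstrap over time blocks within each walker."""
    out = []
    for t in np.unique(traj_index):
        rows = np.where(traj_index == t)[0]
        order = rows[np.argsort(frame_index[rows], kind="stable")]
        n = order.size
        L = min(max(1, block_frames), n)
        n_blocks = int(np.ceil(n / L))
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + np.arange(L)[None, :]).ravel() % n
        out.append(order[idx[:n]])
    return np.concatenate(out)


def state_populations(
    decomposition: StateDecomposition,
    weights: WeightedFrames,
    kT: float = 1.0,
    *,
    n_boot: int = 200,
    block_frames: int = 200,
    seed: int = 0,
) -> StatePopulations:
    """π per microstate, macrostate probabilities, and pairwise ΔF in kT.

    ΔF(A, B) = -kT ln(P_A / P_B); uncertainties are circular block-bootstrap
    SDs (blocks of frames within each walker, respecting autocorrelation).
    A macrostate with zero weight yields an infinite ΔF marker and a
    warning, not an exception.
    """
    labels = decomposition.microstate_label
    w = weights.weights
    pi, groups = _group_probs(decomposition, labels, w)

    macros = decomposition.macrostates
    boot = {m: [] for m in macros}
    rng = stream(seed, 4242)
    for _ in range(n_boot):
        idx = _block_resample_indices(
            weights.traj_index, weights.frame_index, block_frames, rng
        )
        wb = w[idx]
        wb = wb / wb.sum()
        _, gb = _group_probs(decomposition, labels[idx], wb)
        for m in macros:
            boot[m].append(gb.get(m, 0.0))
    boot = {m: np.asarray(v) for m, v in boot.items()}

    delta = {}
    for a in macros:
        for b in macros:
            if a == b:
                continue
            pa, pb = groups[a], groups[b]
            if pa == 0.0 or pb == 0.0:
                warnings.warn(f"macrostate with zero weight in ΔF({a},{b}); reporting ±inf")
                val = np.inf if pa == 0.0 else -np.inf
                delta[(a, b)] = (float(val), float("nan"))
                continue
            with np.errstate(divide="ignore"):
                samples = -kT * np.log(boot[a] / boot[b])
            samples = samples[np.isfinite(samples)]
            sd = float(samples.std(ddof=1)) if samples.size > 1 else float("nan")
            delta[(a, b)] = (float(-kT * np.log(pa / pb)), sd)
    return StatePopulations(pi=pi, group_probability=groups, delta_F_groups=delta, kT=kT)


def structural_adjacency(
    decomposition: StateDecomposition,
    surface: PotentialSurface,
    *,
    contact_threshold: float = 2.0,
    extension_bin_width: float = 1.25,
    anchor: float | None = None,
    n_grid: int = 4001,
) -> np.ndarray:
    """Adjacency of microstates whose CV supports touch.

    Because every fingerprint feature is an interval condition on the exit
    coordinate, each microstate occupies one or two CV intervals; states are
    structurally adjacent iff those supports share a boundary.  Used to prune
    spurious long-range edges from observed connectivity: over one short lag
    the ligand cannot cross an entire state without being seen inside it.
    """
    sg = np.linspace(surface.domain[0, 0], surface.domain[0, 1], n_grid)
    fp, _ = featurize(
        sg,
        surface,
        contact_threshold=contact_threshold,
        extension_bin_width=extension_bin_width,
        anchor=anchor,
    )
    lab = decomposition.assign(fp)
    n = decomposition.n_microstates
    adj = np.eye(n, dtype=bool)
    adj[lab[:-1], lab[1:]] = True
    return adj | adj.T


def connectivity(
    label_seqs: list[np.ndarray],
    decomposition: StateDecomposition,
    lag: int,
) -> np.ndarray:
    """Boolean symmetric adjacency: states seen to interconvert within ``lag``.

    States i, j are adjacent iff a transition i→j or j→i occurs within
    ``lag`` frames in any walker's label sequence; the diagonal is true.
    """
    if lag < 1:
        raise InvalidParameterError("lag must be >= 1")
    n = decomposition.n_microstates
    adj = np.eye(n, dtype=bool)
    max_len = max((len(s) for s in label_seqs), default=0)
    if lag >= max_len:
        raise InvalidParameterError(f"lag {lag} exceeds the longest trajectory ({max_len} frames)")
    for seq in label_seqs:
        seq = np.asarray(seq, dtype=int)
        for delta in range(1, min(lag, len(seq) - 1) + 1):
            a, b = seq[:-delta], seq[delta:]
            adj[a, b] = True
    return adj | adj.T
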