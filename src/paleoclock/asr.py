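"""Marginal ancestral sequence reconstruction on a fixed tree.

For a target internal node, the marginal posterior of each site's ancestral
residue is computed by combining the inside (pruning) partial likelihood of
the clade below the node with the outside likelihood of everything above it,
per discrete-gamma category.  Indels are reconstructed separately as a
binary presence/absence character, either by maximum likelihood under a
symmetric two-state Markov model (residue emitted where the posterior
presence probability clears a cutoff, 0.7 by default) or by Fitch parsimony
with ties resolved to "present".  Reference-coordinate mapping and
reconstruction-agreement statistics support comparing reconstructions made
under different substitution models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Alignment, GAP
from .distances import pairwise_identity
from .substitution import SubstitutionModel, AA_ORDER, binary_gap_model
from .trees import TimeTree, NO_PARENT
from .clock import PruningEngine

#: Alphabetical residue order used for deterministic MAP tie-breaking.
_ALPHABETICAL = sorted(AA_ORDER)


@dataclass
class AncestralReconstruction:
    """Per-site ancestral state posteriors at one target node.

    ``posterior`` has shape (sites, 20) over :data:`AA_ORDER`; rows sum to 1.
    ``indel_mask`` is True where the ancestral residue is inferred present;
    masked (absent) sites carry ``-`` in ``map_sequence``.
    """

    target_node: int
    posterior: np.ndarray
    map_sequence: str
    indel_mask: np.ndarray
    method: str

    def __post_init__(self):
        sums = self.posterior.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("site posteriors must sum to 1")
        if len(self.map_sequence) != self.posterior.shape[0]:
            raise ValueError("map_sequence length mismatch")

    @property
    def map_pp(self) -> np.ndarray:
        """Posterior probability of the MAP residue at each site."""
        return self.posterior.max(axis=1)


def _branch_subs_array(tree: TimeTree, branch_subs) -> np.ndarray:
    if branch_subs is None:
        subs = np.zeros(tree.n_nodes)
        for v in range(tree.n_nodes):
            if tree.parent[v] != NO_PARENT:
                subs[v] = tree.branch_subs(v)
        return subs
    if isinstance(branch_subs, dict):
        subs = np.zeros(tree.n_nodes)
        for v, t in branch_subs.items():
            subs[v] = t
        return subs
    return np.asarray(branch_subs, dtype=float)


def _outside_at(engine: PruningEngine, target: int) -> np.ndarray:
    """Outside likelihood (K, sites, states) of the data above ``target``.

    outside(root) is the stationary distribution; descending to a child c of
    u, outside(c) = P_c^T (outside(u) * prod of sibling branch factors).
    """
    tree = engine.tree
    path = []
    v = target
    while v != tree.root:
        path.append(v)
        v = tree.parent[v]
    path.reverse()  # root-side first

    pi = engine._pi
    outside = np.broadcast_to(
        pi[None, None, :], (engine.k, engine.n_sites, pi.size)
    ).copy()
    current = tree.root
    for child in path:
        acc = outside
        for sib in tree.children[current]:
            if sib == child:
                continue
            acc = acc * engine.branch_m(sib)
        p = engine.transition_matrices(child)  # (K, states, states)
        outside = np.matmul(acc, p)  # sum over parent state: acc @ P
        current = child
    return outside


def _map_residue(pp_row: np.ndarray) -> str:
    top = pp_row.max()
    tied = [AA_ORDER[i] for i in np.nonzero(pp_row >= top - 1e-12)[0]]
    return min(tied, key=_ALPHABETICAL.index)


def marginal_asr(
    alignment: Alignment,
    tree: TimeTree,
    model: SubstitutionModel,
    target_node: int,
    branch_subs=None,
    indel_mask: np.ndarray | None = None,
) -> AncestralReconstruction:
    """Marginal posterior of ancestral residues at ``target_node``.

    Branch lengths (expected substitutions/site) are taken from the tree's
    rates x durations unless ``branch_subs`` (dict or array by child node)
    is given.  Gaps are missing data for the residue process; the optional
    ``indel_mask`` (from :func:`reconstruct_indels`) blanks absent sites in
    the MAP sequence.
    """
    if not tree.children[target_node]:
        raise ValueError(f"target node {target_node} is a leaf")
    subs = _branch_subs_array(tree, branch_subs)
    engine = PruningEngine(alignment, tree, model)
    engine.initialise(subs)
    inside = engine.node_partial(target_node)  # (K, S, 20)
    outside = _outside_at(engine, target_node)
    joint = (inside * outside).sum(axis=0)  # per pattern; uniform category prior
    total = joint.sum(axis=1, keepdims=True)
    posterior = (joint / np.maximum(total, 1e-300))[engine.pattern_inverse]

    n_sites = alignment.length
    mask = (
        np.ones(n_sites, dtype=bool) if indel_mask is None
        else np.asarray(indel_mask, dtype=bool)
    )
    residues = [
        _map_residue(posterior[i]) if mask[i] else GAP for i in range(n_sites)
    ]
    tag = f"{model.matrix_id}+G{model.n_categories}" + (
        "" if indel_mask is None else "+indel"
    )
    return AncestralReconstruction(
        target_node=target_node,
        posterior=posterior,
        map_sequence="".join(residues),
        indel_mask=mask,
        method=tag,
    )


def _gap_characters(alignment: Alignment, tree: TimeTree) -> np.ndarray:
    """(leaf node -> site) presence (1) / absence (0) matrix rows."""
    lookup = dict(alignment.records)
    chars = {}
    for leaf in tree.leaves:
        seq = lookup[tree.names[leaf]]
        chars[leaf] = np.array([0 if ch == GAP else 1 for ch in seq])
    return chars


def reconstruct_indels(
    alignment: Alignment,
    tree: TimeTree,
    target_node: int,
    mode: str = "ML",
    cutoff: float = 0.7,
    branch_subs=None,
    rate_scale: float = 1.0,
) -> np.ndarray:
    """Presence/absence mask of the ancestral sites at ``target_node``.

    ``mode="ML"``: gap presence evolves as a symmetric 2-state Markov
    character over branch lengths ``rate_scale`` x the tree's substitution
    branch lengths; a site is present iff its marginal posterior presence
    probability is at least ``cutoff``.  ``mode="PARSIMONY"``: Fitch small
    parsimony with target-node ties resolved to present.
    """
    mode = mode.upper()
    if mode not in ("ML", "PARSIMONY"):
        raise ValueError("mode must be 'ML' or 'PARSIMONY'")
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if not tree.children[target_node]:
        raise ValueError(f"target node {target_node} is a leaf")
    chars = _gap_characters(alignment, tree)
    n_sites = alignment.length

    if mode == "PARSIMONY":
        # Fitch up-pass: state sets as 2-bit masks (1=absent, 2=present)
        up = {}
        for v in tree.postorder():
            if not tree.children[v]:
                up[v] = np.where(chars[v] == 1, 2, 1)
            else:
                acc = None
                for c in tree.children[v]:
                    acc = up[c] if acc is None else acc
                inter = up[tree.children[v][0]].copy()
                union = up[tree.children[v][0]].copy()
                for c in tree.children[v][1:]:
                    inter &= up[c]
                    union |= up[c]
                up[v] = np.where(inter != 0, inter, union)
        # down-pass to the target along the root path
        path = []
        v = target_node
        while v != NO_PARENT:
            path.append(v)
            v = tree.parent[v]
        path.reverse()
        final = None
        for v in path:
            sets = up[v]
            if final is None:
                chosen = sets
            else:
                chosen = np.where((sets & final) != 0, sets & final, sets)
            # resolve remaining ambiguity (mask 3) to "present"
            final = np.where(chosen == 3, 2, chosen)
        return final == 2

    # ML mode: 2-state pruning with the spectral pieces of the gap chain
    w, u, uinv, pi = binary_gap_model()
    subs = _branch_subs_array(tree, branch_subs) * rate_scale

    def p_matrix(t: float) -> np.ndarray:
        p = (u * np.exp(w * t)[None, :]) @ uinv
        return np.clip(p, 0.0, 1.0)

    inside = {}
    for v in tree.postorder():
        if not tree.children[v]:
            part = np.zeros((n_sites, 2))
            part[np.arange(n_sites), chars[v]] = 1.0
            inside[v] = part
        else:
            acc = np.ones((n_sites, 2))
            for c in tree.children[v]:
                acc *= inside[c] @ p_matrix(subs[c]).T
            inside[v] = acc
    # outside pass down the root path
    outside = np.broadcast_to(pi[None, :], (n_sites, 2)).copy()
    path = []
    v = target_node
    while v != tree.root:
        path.append(v)
        v = tree.parent[v]
    path.reverse()
    current = tree.root
    for child in path:
        acc = outside
        for sib in tree.children[current]:
            if sib == child:
                continue
            acc = acc * (inside[sib] @ p_matrix(subs[sib]).T)
        outside = acc @ p_matrix(subs[child])
        current = child
    joint = inside[target_node] * outside
    pp_present = joint[:, 1] / np.maximum(joint.sum(axis=1), 1e-300)
    return pp_present >= cutoff


def map_reference_site(
    alignment: Alignment, reference_id: str, reference_position: int
) -> int:
    """0-based alignment column holding the reference row's 1-based ungapped
    residue ``reference_position``."""
    seq = alignment.sequence(reference_id)
    if reference_position < 1:
        raise ValueError("reference_position is 1-based (must be >= 1)")
    count = 0
    for col, ch in enumerate(seq):
        if ch != GAP:
            count += 1
            if count == reference_position:
                return col
    raise IndexError(
        f"reference {reference_id!r} has only {count} residues; "
        f"position {reference_position} is out of range"
    )


def map_column_to_reference(
    alignment: Alignment, reference_id: str, column: int
) -> tuple[str, int] | None:
    """Inverse mapping: (residue, 1-based ungapped position) at ``column``,
    or None when the reference row is gapped there."""
    seq = alignment.sequence(reference_id)
    if not 0 <= column < len(seq):
        raise IndexError(f"column {column} outside alignment of {len(seq)}")
    if seq[column] == GAP:
        return None
    position = sum(1 for ch in seq[: column + 1] if ch != GAP)
    return seq[column], position


@dataclass
class ReconstructionComparison:
    """Agreement statistics across a set of reconstructions."""

    mean_identity: float
    sd_identity: float
    pairwise_identities: np.ndarray
    mean_map_pp: np.ndarray  # per reconstruction, mean MAP PP over unmasked sites


def compare_reconstructions(
    reconstructions, reference_sequence: str | None = None
) -> ReconstructionComparison:
    """Mean pairwise identity (± sd) of MAP sequences on mutually unmasked
    sites, plus per-reconstruction mean posterior support.

    With ``reference_sequence`` given (an aligned row on the same column
    space), each reconstruction is instead compared against the reference.
    """
    recs = list(reconstructions)
    if reference_sequence is None and len(recs) < 2:
        raise ValueError("need >= 2 reconstructions (or a reference)")
    lengths = {len(r.map_sequence) for r in recs}
    if reference_sequence is not None:
        lengths.add(len(reference_sequence))
    if len(lengths) != 1:
        raise ValueError("reconstructions span different column spaces")

    idents = []
    if reference_sequence is not None:
        for r in recs:
            idents.append(pairwise_identity(r.map_sequence, reference_sequence))
    else:
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                idents.append(
                    pairwise_identity(recs[i].map_sequence, recs[j].map_sequence)
                )
    idents = np.array(idents)
    pps = np.array(
        [
            r.map_pp[r.indel_mask].mean() if r.indel_mask.any() else np.nan
            for r in recs
        ]
    )
    sd = float(idents.std(ddof=1)) if idents.size > 1 else 0.0
    return ReconstructionComparison(
        mean_identity=float(idents.mean()),
        sd_identity=sd,
        pairwise_identities=idents,
        mean_map_pp=pps,
    )


def site_table(
    reconstruction: AncestralReconstruction,
    alignment: Alignment | None = None,
    reference_id: str | None = None,
):
    """Per-site report: column, reference position, MAP residue, top-3 PPs,
    indel state."""
    import pandas as pd

    rows = []
    for col in range(reconstruction.posterior.shape[0]):
        pp = reconstruction.posterior[col]
        top3 = np.argsort(pp)[::-1][:3]
        ref = ""
        if alignment is not None and reference_id is not None:
            hit = map_column_to_reference(alignment, reference_id, col)
            ref = "gap" if hit is None else f"{hit[0]}{hit[1]}"
        rows.append(
            {
                "column_1based": col + 1,
                "reference_site": ref,
                "present": bool(reconstruction.indel_mask[col]),
                "map_residue": reconstruction.map_sequence[col],
                "top1": f"{AA_ORDER[top3[0]]}:{pp[top3[0]]:.4f}",
                "top2": f"{AA_ORDER[top3[1]]}:{pp[top3[1]]:.4f}",
                "top3": f"{AA_ORDER[top3[2]]}:{pp[top3[2]]:.4f}",
            }
        )
    return pd.DataFrame(rows)
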