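"""CD-HIT style greedy incremental identity clustering."""
from __future__ import annotations

from dataclasses import dataclass, field

from famforge.profile_search.align import ScoringScheme, sequence_identity


@dataclass
class IdentityCluster:
    """One greedy cluster: a representative and the members it absorbed."""

    representative: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 0.9

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_identity_cluster(
    sequences: dict[str, str],
    threshold: float,
    scheme: ScoringScheme | None = None,
) -> list[IdentityCluster]:
    """Greedy incremental clustering, longest sequence first.

    Sequences are processed in decreasing length (ties broken by id).  Each
    sequence joins the first existing cluster — in cluster-creation order —
    whose representative it matches at identity >= ``threshold`` (identical
    aligned residues over the shorter sequence length, from global
    alignment; the boundary is inclusive); otherwise it founds a new
    cluster.  The result partitions the input.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    clusters: list[IdentityCluster] = []
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    for seq_id in order:
        seq = sequences[seq_id]
        placed = False
        for cluster in clusters:
            ident = sequence_identity(seq, sequences[cluster.representative], scheme)
            if ident >= threshold:
                cluster.member_ids.append(seq_id)
                placed = True
                break
        if not placed:
            clusters.append(
                IdentityCluster(seq_id, member_ids=[seq_id], threshold=threshold)
            )
    return clusters
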