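"""Independent oracles and toy builders shared between test modules."""

import numpy as np

import phenoclust as pc
from phenoclust.cluster import ClusterModel, _pairwise


def dbscan_reachability_oracle(X, eps, min_samples, metric):
    """Textbook DBSCAN by queue expansion over the reachability graph."""
    D = _pairwise(X, X, metric)
    n = len(X)
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]  # includes self
    labels = [None] * n
    cluster = 0
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbors[i])
        while queue:
            j = queue.pop()
            if labels[j] is None:
                labels[j] = cluster
                if core[j]:
                    queue.extend(k for k in neighbors[j] if labels[k] is None)
    return np.array([lab if lab is not None else -1 for lab in labels])


def silhouette_oracle(X, labels, metric):
    """Mean silhouette (b - a) / max(a, b) by direct double loop."""
    D = _pairwise(X, X, metric)
    vals = []
    for i in range(len(X)):
        same = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not same.any():
            vals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in set(labels) if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def toy_model_and_vectors(counts):
    """Vectors plus a cluster model realizing given (cluster, tag) counts."""
    vectors, labels, index = [], [], []
    i = 0
    for (cluster, tag), n in counts.items():
        for _ in range(n):
            v = pc.RateVector(
                experiment_id=f"e{i}", time=1.0, mu=0.1,
                rates={2: 0.0, 3: -1.0},
                concentrations_at_t={1: 0.5},
                tags={"cond": tag},
            )
            vectors.append(v)
            labels.append(cluster)
            index.append((v.experiment_id, v.time))
            i += 1
    k = max(c for c, _ in counts)
    model = ClusterModel(
        method="kmeans", metric="cd", k=k,
        labels=np.array(labels), index=index, z_centroids=None,
        raw_centroids=np.zeros((k, 3)),
        dimension_labels=["mu", "Glc", "Gly"],
    )
    return model, vectors
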