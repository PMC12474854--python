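import numpy as np
import pandas as pd


def random_matched_sets(seed, n_sets=50, beta=(0.03, 0.5), mean_x=25.0, sd_x=8.0):
    """Synthetic matched sets drawn directly from the conditional model."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    rows = []
    for s in range(n_sets):
        m = int(rng.integers(4, 6))
        x = rng.normal(mean_x, sd_x, m)
        z = rng.normal(0.0, 1.0, m)
        eta = beta[0] * x + beta[1] * z
        p = np.exp(eta - eta.max())
        p /= p.sum()
        case = rng.choice(m, p=p)
        for j in range(m):
            rows.append(
                {"set_id": s, "is_case": bool(j == case), "x": x[j], "z": z[j]}
            )
    return pd.DataFrame(rows)
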