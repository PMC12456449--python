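"""Regenerate the packaged synthetic example datasets.

The packaged CSVs under ``src/xrrmeta/datasets/`` are *synthetic
stand-ins* for two published rare-event meta-analyses (a 48-trial drug
safety study with MI and cardiovascular-death endpoints, and a 29-study
face-mask transmission review).  They are drawn from the package's own
Poisson–Gamma generator with fixed seeds, shaped to match the published
studies qualitatively — study count, the spread of arm sizes including
two very large trials, event rarity, double-zero prevalence — but they
are NOT the published study data and reproduce no published result.

Run from the repository root:  python scripts/make_synthetic_fixtures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xrrmeta.model import shape_from_moments

OUT = Path(__file__).resolve().parents[1] / "src" / "xrrmeta" / "datasets"


def _draw_counts(rng, n1, n2, mu, v, base_rate):
    """Arm counts under the Poisson-Gamma model with contrast law (mu, v)."""
    a, b = shape_from_moments(mu, v)
    rate = a / base_rate
    lam1 = rng.gamma(a, scale=1.0 / rate, size=len(n1))
    lam2 = rng.gamma(b, scale=1.0 / rate, size=len(n1))
    y1 = np.minimum(rng.poisson(n1 * lam1), n1)
    y2 = np.minimum(rng.poisson(n2 * lam2), n2)
    return y1, y2


def make_drug_safety(rng):
    """48 two-arm trials: 45 small-to-medium plus two very large and one large."""
    n_small = 45
    n1 = np.round(np.exp(rng.uniform(np.log(100), np.log(450), size=n_small))).astype(int)
    # control arms mostly smaller (1:1 or 2:1 randomization)
    ratio = rng.choice([1.0, 2.0], size=n_small, p=[0.4, 0.6])
    n2 = np.maximum(20, np.round(n1 / ratio)).astype(int)
    n1 = np.concatenate([n1, [1456, 2635, 1501]])
    n2 = np.concatenate([n2, [2895, 2634, 2502]])
    order = rng.permutation(len(n1))
    return n1[order], n2[order]


def make_facemask(rng):
    """29 observational studies with widely varying sizes."""
    n1 = np.round(np.exp(rng.uniform(np.log(30), np.log(700), size=29))).astype(int)
    n2 = np.round(n1 * np.exp(rng.uniform(-0.7, 0.7, size=29))).astype(int)
    return n1, np.maximum(10, n2)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20240916)

    n1, n2 = make_drug_safety(rng)
    # harmful contrast, high heterogeneity, MI-like rarity (~0.6%/arm)
    y1, y2 = _draw_counts(rng, n1, n2, mu=0.62, v=0.03, base_rate=0.007)
    _write("rosiglitazone_mi_synthetic.csv", n1, n2, y1, y2)
    # CVD-like: rarer still
    y1, y2 = _draw_counts(rng, n1, n2, mu=0.68, v=0.03, base_rate=0.0030)
    _write("rosiglitazone_cvd_synthetic.csv", n1, n2, y1, y2)

    n1, n2 = make_facemask(rng)
    # strongly protective contrast, infection-like base rate in controls
    y1, y2 = _draw_counts(rng, n1, n2, mu=0.20, v=0.01, base_rate=0.02)
    _write("facemask_synthetic.csv", n1, n2, y1, y2)


def _write(name, n1, n2, y1, y2):
    frame = pd.DataFrame(
        {
            "label": [f"synthetic_{i + 1}" for i in range(len(n1))],
            "y1": y1,
            "n1": n1,
            "y2": y2,
            "n2": n2,
        }
    )
    path = OUT / name
    frame.to_csv(path, index=False)
    dz = int(((y1 == 0) & (y2 == 0)).sum())
    print(f"{name}: {len(n1)} studies, {dz} double-zero, {y1.sum()}/{y2.sum()} events")


if __name__ == "__main__":
    main()
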