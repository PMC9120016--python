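"""Regenerate the bundled generic 25-letter prototype table (package data)."""
import numpy as np
from sklearn.cluster import KMeans
from dynevo.couplings import fragment_descriptors

rng = np.random.default_rng(20260927)

def helix(n):
    i = np.arange(n); th = np.radians(100.0)*i
    return np.stack([0.23*np.cos(th), 0.23*np.sin(th), 0.15*i], 1)

def strand(n):
    i = np.arange(n)
    x = 0.333*i
    y = 0.09*(-1)**i
    return np.stack([x, y, 0.02*(-1)**(i//2)], 1)

def coil(n, r):
    # random walk with ~0.38 nm steps and mild angular persistence
    pts = [np.zeros(3)]
    d = r.standard_normal(3); d /= np.linalg.norm(d)
    for _ in range(n-1):
        d = d + 0.9*r.standard_normal(3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + 0.38*d)
    return np.array(pts)

frags = []
for _ in range(1500):
    for builder in (helix, strand):
        c = builder(4) + rng.normal(0, 0.025, (4, 3))
        frags.append(fragment_descriptors(c[None])[0, 0])
for _ in range(3000):
    c = coil(4, rng)
    frags.append(fragment_descriptors(c[None])[0, 0])
X = np.array(frags)
km = KMeans(n_clusters=25, random_state=0, n_init=10).fit(X)
centers = km.cluster_centers_[np.lexsort(km.cluster_centers_.T[::-1])]
with open("src/dynevo/data/alphabet25.tsv", "w") as fh:
    fh.write("letter\ttheta123\ttheta234\ttheta134\tcos_tau\tsin_tau\n")
    for k, c in enumerate(centers):
        fh.write(f"{k}\t" + "\t".join(f"{v:.6f}" for v in c) + "\n")
print("wrote", X.shape, "->", centers.shape)
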