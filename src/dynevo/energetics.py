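"""Contact frustration: native contact energies versus identity decoys.

Each native Cα contact (i, j) is scored against a distribution of decoy
energies obtained by randomizing the identities of both contacting
residues.  The frustration index is the z-score

    index = (mean(E_decoy) - E_native) / sd(E_decoy)

so that a contact whose native energy sits at the favourable (low) end of
the decoy distribution scores positive.  Contacts with index > 0.78 are
classified relaxed (minimally frustrated) and index < -1 stressed (highly
frustrated); everything between is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from dynevo.structio import ContactMap, ResidueKey

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

RELAXED_THRESHOLD = 0.78
STRESSED_THRESHOLD = -1.0

# Kyte–Doolittle hydropathy, used to build the default contact potential
_KD_SCALE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


@dataclass
class ContactEnergyModel:
    """Symmetric 20×20 dimensionless contact potential."""

    pair_energy: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.pair_energy = np.asarray(self.pair_energy, float)
        if self.pair_energy.shape != (20, 20):
            raise ValueError("pair_energy must be 20×20")
        if not np.allclose(self.pair_energy, self.pair_energy.T):
            raise ValueError("pair_energy must be symmetric")
        if not np.all(np.isfinite(self.pair_energy)):
            raise ValueError("non-finite energies")

    def energy(self, a: str, b: str) -> float:
        return float(self.pair_energy[AA_INDEX[a], AA_INDEX[b]])

    @classmethod
    def default(cls) -> "ContactEnergyModel":
        """Hydrophobicity-product contact potential.

        e(a, b) = -h(a)·h(b)/25 with h the Kyte–Doolittle hydropathy:
        hydrophobic–hydrophobic contacts are favourable (negative), in the
        spirit of knowledge-based contact potentials.  A deliberately simple
        built-in default; any 20×20 table can be injected instead.
        """
        h = np.array([_KD_SCALE[a] for a in AMINO_ACIDS])
        return cls(pair_energy=-np.outer(h, h) / 25.0, name="kd_hydropathy_product")


@dataclass
class FrustrationProfile:
    """Per-contact frustration indices and classes."""

    table: pd.DataFrame
    # columns: chainA, resA, chainB, resB, native_energy, decoy_mean,
    #          decoy_sd, index, class, flagged
    h: int
    seed: int

    def __len__(self) -> int:
        return len(self.table)

    def class_of(self, pair: tuple[ResidueKey, ResidueKey]) -> str:
        (ca, ra), (cb, rb) = pair
        t = self.table
        m = (
            ((t.chainA == ca) & (t.resA == ra) & (t.chainB == cb) & (t.resB == rb))
            | ((t.chainA == cb) & (t.resA == rb) & (t.chainB == ca) & (t.resB == ra))
        )
        hit = t[m]
        if hit.empty:
            raise KeyError(f"contact {pair} not in profile")
        return str(hit["class"].iloc[0])


def classify(index: float) -> str:
    if not np.isfinite(index):
        return "neutral"
    if index > RELAXED_THRESHOLD:
        return "relaxed"
    if index < STRESSED_THRESHOLD:
        return "stressed"
    return "neutral"


def frustration(
    c: ContactMap,
    seq: Mapping[ResidueKey, str],
    model: ContactEnergyModel | None = None,
    h: int = 400,
    seed: int = 0,
) -> FrustrationProfile:
    """Frustration index for every contact in *c*.

    Decoys replace both residue identities by combinations drawn uniformly
    without replacement from the 400 ordered amino-acid pairs; ``h = 400``
    is therefore the exhaustive enumeration.  ``decoy_sd`` is the
    population standard deviation (1/h normalization).  A zero decoy sd
    leaves the index undefined (NaN), the class neutral, and the contact
    flagged.
    """
    if h < 2:
        raise ValueError("h must be ≥ 2")
    if h > 400:
        raise ValueError("h cannot exceed the 400 identity combinations")
    if model is None:
        model = ContactEnergyModel.default()
    rng = np.random.default_rng(seed)
    flat = model.pair_energy.ravel()
    rows = []
    for a, b in c.pairs:
        aa_a = seq[a]
        aa_b = seq[b]
        if aa_a not in AA_INDEX or aa_b not in AA_INDEX:
            raise ValueError(f"non-standard residue in contact {(a, b)}")
        native = model.energy(aa_a, aa_b)
        if h == 400:
            decoys = flat
        else:
            decoys = flat[rng.choice(400, size=h, replace=False)]
        mu = float(decoys.mean())
        sd = float(decoys.std(ddof=0))
        if sd == 0:
            idx = np.nan
            flagged = True
        else:
            idx = (mu - native) / sd
            flagged = False
        rows.append(
            (
                a[0], a[1], b[0], b[1], native, mu, sd, idx,
                classify(idx), flagged,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chainA", "resA", "chainB", "resB", "native_energy",
            "decoy_mean", "decoy_sd", "index", "class", "flagged",
        ],
    )
    return FrustrationProfile(table=table, h=h, seed=seed)


def interface_frustration_summary(
    p: FrustrationProfile, c: ContactMap
) -> pd.DataFrame:
    """Contingency counts of frustration class by interface class.

    Rows: every interface class present in *c* (zero rows retained);
    columns: relaxed / neutral / stressed.
    """
    classes = ["relaxed", "neutral", "stressed"]
    iface_order = []
    for pair in c.pairs:
        ic = c.interface_class[pair]
        if ic not in iface_order:
            iface_order.append(ic)
    lookup: dict[tuple, str] = {}
    for row in p.table.itertuples():
        key = ((row.chainA, row.resA), (row.chainB, row.resB))
        lookup[key] = row[9]  # class column
        lookup[(key[1], key[0])] = row[9]
    out = pd.DataFrame(0, index=iface_order, columns=classes)
    for pair in c.pairs:
        ic = c.interface_class[pair]
        fc = lookup[pair]
        out.loc[ic, fc] += 1
    out.index.name = "interface"
    return out
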