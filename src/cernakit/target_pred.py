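"""miRNA seed-site discovery and miRNA–target candidate filtering.

Canonical seed sites are exact Watson–Crick matches to the miRNA seed
(positions 2–8, 5'→3'), with no G:U wobbles. Writing comp(Nk) for the
complement of miRNA position k, a site in the target (5'→3') reads

    6mer      comp(N7)..comp(N2)
    7mer-m8   comp(N8) comp(N7)..comp(N2)
    7mer-A1   comp(N7)..comp(N2) A
    8mer      comp(N8) comp(N7)..comp(N2) A

(the A opposite position 1 is an identity requirement, not a pairing).
Strict mode — the only mode the pipeline's upstream prediction
requires — reports 7mer-m8 and 8mer sites only.

Candidate pairs then pass two expression filters: the miRNA and its
target must be dysregulated in opposite directions (miRNA up ⇒ target
down and vice versa), and their Pearson correlation across all cohort
samples (tumor + normal, transformed scale) must be at or below the
anti-correlation threshold (default −0.4, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Thresholds
from .matrix import ExpressionMatrix, ValidationError

_RNA = set("ACGU")
_COMP = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
STRICT_SITE_TYPES = ("7mer-m8", "8mer")


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - _RNA
    if bad:
        raise ValidationError(
            f"{what}: non-RNA characters {sorted(bad)} (expected A/C/G/U)"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMP)[::-1]


@dataclass
class MicroRNA:
    mirna_id: str
    sequence: str  # mature sequence, 5'->3'

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if len(self.sequence) < 18:
            raise ValidationError(
                f"{self.mirna_id}: mature miRNA shorter than 18 nt"
            )
        _check_rna(self.sequence, self.mirna_id)

    @property
    def seed6(self) -> str:
        """Positions 2-7."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Positions 2-8."""
        return self.sequence[1:8]


@dataclass
class TargetSite:
    target_id: str
    mirna_id: str
    position: int  # 1-based start of the site on the target
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValidationError(f"unknown site type {self.site_type!r}")


def seed_sites(
    mirna: MicroRNA,
    target_seq: str,
    target_id: str = "",
    strict: bool = True,
) -> list:
    """Scan a target sequence for canonical seed sites.

    Returns one :class:`TargetSite` per match position, classified as
    the strongest applicable type; strict mode keeps only 7mer-m8 and
    8mer sites.
    """
    target_seq = target_seq.upper().replace("T", "U")
    _check_rna(target_seq, target_id or "target")
    core = revcomp(mirna.seed6)  # comp(N7)..comp(N2)
    m8_base = revcomp(mirna.seed7)[0]  # comp(N8)
    sites = []
    start = target_seq.find(core)
    while start != -1:
        has_m8 = start > 0 and target_seq[start - 1] == m8_base
        a1_pos = start + len(core)
        has_a1 = a1_pos < len(target_seq) and target_seq[a1_pos] == "A"
        if has_m8 and has_a1:
            stype, pos0 = "8mer", start - 1
        elif has_m8:
            stype, pos0 = "7mer-m8", start - 1
        elif has_a1:
            stype, pos0 = "7mer-A1", start
        else:
            stype, pos0 = "6mer", start
        if not strict or stype in STRICT_SITE_TYPES:
            sites.append(TargetSite(target_id, mirna.mirna_id, pos0 + 1, stype))
        start = target_seq.find(core, start + 1)
    return sites


def scan_sites(
    mirnas: list, targets: dict, strict: bool = True
) -> list:
    """All seed sites of every miRNA in every target sequence."""
    out = []
    for m in mirnas:
        for tid, seq in targets.items():
            out.extend(seed_sites(m, seq, target_id=tid, strict=strict))
    return out


# ---------------------------------------------------------------------------
# candidate assembly and filtering
# ---------------------------------------------------------------------------

_EVIDENCE_MAP = {"validated": "validated_db", "predicted": "predicted_db"}

PAIR_COLUMNS = [
    "mirna_id", "target_id", "target_class", "evidence",
    "mirna_dir", "target_dir",
]


def build_candidates(
    de_mirnas: dict,
    de_ncrnas: dict,
    de_mrnas: dict,
    sites: list,
    external: pd.DataFrame | None = None,
    ncrna_classes: dict | None = None,
) -> pd.DataFrame:
    """Assemble miRNA–target candidate pairs with DE annotations.

    Parameters
    ----------
    de_mirnas, de_ncrnas, de_mrnas
        Maps id -> direction ('up'/'down') for dysregulated molecules.
    sites
        Seed sites on ncRNA sequences (lncRNA/circRNA targets).
    external
        Normalised external mRNA–miRNA table (validated/predicted).
    ncrna_classes
        Map ncRNA id -> 'lncRNA'/'circRNA'; defaults to 'lncRNA'.

    Sites or table rows whose miRNA or target lacks a DE call are
    dropped (one warning with counts). Duplicate (miRNA, mRNA) rows
    across sources collapse into one pair with merged evidence.
    """
    ncrna_classes = ncrna_classes or {}
    rows = {}
    dropped = 0
    for s in sites:
        if s.mirna_id not in de_mirnas or s.target_id not in de_ncrnas:
            dropped += 1
            continue
        key = (s.mirna_id, s.target_id)
        if key not in rows:
            rows[key] = {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "target_class": ncrna_classes.get(s.target_id, "lncRNA"),
                "evidence": {"seed"},
                "mirna_dir": de_mirnas[s.mirna_id],
                "target_dir": de_ncrnas[s.target_id],
            }
    if external is not None and len(external):
        for rec in external.itertuples(index=False):
            if rec.mirna_id not in de_mirnas or rec.target_id not in de_mrnas:
                dropped += 1
                continue
            key = (rec.mirna_id, rec.target_id)
            ev = _EVIDENCE_MAP.get(rec.evidence, rec.evidence)
            if key in rows:
                rows[key]["evidence"].add(ev)
            else:
                rows[key] = {
                    "mirna_id": rec.mirna_id,
                    "target_id": rec.target_id,
                    "target_class": "mRNA",
                    "evidence": {ev},
                    "mirna_dir": de_mirnas[rec.mirna_id],
                    "target_dir": de_mrnas[rec.target_id],
                }
    if dropped:
        warnings.warn(
            f"{dropped} candidate pairs dropped: molecule without a "
            "dysregulation call"
        )
    recs = [
        {**r, "evidence": "+".join(sorted(r["evidence"]))}
        for r in rows.values()
    ]
    return pd.DataFrame(recs, columns=PAIR_COLUMNS)


def filter_pairs(
    pairs: pd.DataFrame,
    expression: ExpressionMatrix,
    thresholds: Thresholds | None = None,
    min_samples: int = 4,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Opposite-direction and anti-correlation filter for candidates.

    Retains pairs whose miRNA and target are dysregulated in opposite
    directions and whose Pearson correlation across all samples is at
    or below the threshold (inclusive by default; configurable). Pairs
    with fewer than ``min_samples`` shared samples, or with a molecule
    missing from the expression matrix, are dropped with a warning.
    With ``keep_all`` the full table is returned with a
    ``passes_filters`` column instead.
    """
    thresholds = thresholds or Thresholds()
    if len(pairs) == 0:
        out = pairs.copy()
        out["pcc"] = pd.Series(dtype=float)
        out["passes_filters"] = pd.Series(dtype=bool)
        return out
    V = expression.values
    pcc = np.full(len(pairs), np.nan)
    dropped = 0
    for i, rec in enumerate(pairs.itertuples(index=False)):
        if rec.mirna_id not in V.index or rec.target_id not in V.index:
            dropped += 1
            continue
        x = V.loc[rec.mirna_id].to_numpy(dtype=float)
        y = V.loc[rec.target_id].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_samples:
            dropped += 1
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            dropped += 1
            continue
        pcc[i] = np.corrcoef(x[ok], y[ok])[0, 1]
    if dropped:
        warnings.warn(
            f"{dropped} pairs dropped: missing expression or <"
            f"{min_samples} shared samples"
        )
    out = pairs.copy()
    out["pcc"] = pcc
    opposite = (
        ((out["mirna_dir"] == "up") & (out["target_dir"] == "down"))
        | ((out["mirna_dir"] == "down") & (out["target_dir"] == "up"))
    )
    cut = thresholds.pcc_mirna_target
    if thresholds.pcc_mirna_target_inclusive:
        corr_ok = out["pcc"] <= cut
    else:
        corr_ok = out["pcc"] < cut
    out["passes_filters"] = (opposite & corr_ok & out["pcc"].notna())
    if keep_all:
        return out
    return out[out["passes_filters"]].reset_index(drop=True)
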