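"""Multi-platform feature integration by Spearman filtering.

mRNA expression is the anchor platform: copy-number and methylation
features pair with the mRNA of the same gene symbol, microRNAs pair with
their target genes through a user-supplied pairing table. Spearman rank
correlations between each non-mRNA feature and its paired mRNA feature(s)
are computed on training samples only; a feature is retained when its
best-matching absolute correlation clears the platform cutoff (optionally
with a required sign). mRNA features pass through unfiltered. Retained
features from all platforms are concatenated, tagged by platform, into a
single samples x features matrix for the penalized Cox path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import SurvivalOutcome

__all__ = [
    "FeatureMatrix",
    "IntegrationConfig",
    "IntegratedDataset",
    "SpearmanIntegrator",
    "spearman_pairs",
    "filter_features",
    "assemble_integrated",
]

logger = logging.getLogger(__name__)

EXPECTED_SIGN = {"CNA": 1.0, "METH": -1.0, "miRNA": -1.0}


@dataclass
class FeatureMatrix:
    """Samples x features values for one platform."""

    values: pd.DataFrame
    platform: str

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids in {self.platform}: {dups[:5]}")
        if self.values.index.duplicated().any():
            raise ValueError(f"duplicate sample ids in {self.platform}")


@dataclass(frozen=True)
class IntegrationConfig:
    """Per-platform absolute-Spearman cutoffs and sign policy.

    ``sign_policy`` is "any" (magnitude only, the default) or "signed"
    (CNA must correlate positively with mRNA, METH and miRNA negatively).
    ``max_missing`` is the tolerated fraction of missing entries per
    feature before it is dropped; the remainder are median-imputed on
    training samples.
    """

    cutoff_cna: float = 0.3
    cutoff_meth: float = 0.3
    cutoff_mirna: float = 0.2
    sign_policy: str = "any"
    max_missing: float = 0.2

    def __post_init__(self):
        for name in ("cutoff_cna", "cutoff_meth", "cutoff_mirna"):
            c = getattr(self, name)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sign_policy not in ("any", "signed"):
            raise ValueError("sign_policy must be 'any' or 'signed'")

    def cutoff_for(self, platform: str) -> float:
        return {"CNA": self.cutoff_cna, "METH": self.cutoff_meth,
                "miRNA": self.cutoff_mirna}[platform]


@dataclass
class IntegratedDataset:
    """Combined feature space ready for path fitting.

    ``features`` has a (platform, feature) column MultiIndex; ``train``
    is a boolean mask over samples. Standardization statistics (training
    samples only) are stored for leakage checks and reporting.
    """

    features: pd.DataFrame
    outcomes: SurvivalOutcome
    train: np.ndarray
    train_mean: pd.Series
    train_std: pd.Series
    retention: pd.DataFrame


def _rank_z(df: pd.DataFrame) -> pd.DataFrame:
    ranks = df.rank(method="average")
    z = (ranks - ranks.mean()) / ranks.std(ddof=0)
    return z


def spearman_pairs(mrna: FeatureMatrix, other: FeatureMatrix,
                   pairing: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman rho for every (other-platform feature, paired gene).

    CNA/METH features pair with the mRNA feature of the same id;
    microRNAs pair through ``pairing`` (columns ``mirna``/``gene``,
    possibly several genes per microRNA). Ties are handled by average
    ranks. Features with no mapped mRNA gene are excluded with a logged
    count.

    Returns a DataFrame with columns ``feature``, ``gene``, ``rho``.
    """
    if not mrna.values.index.equals(other.values.index):
        raise ValueError("mRNA and other platform must share the sample axis")
    if other.platform == "miRNA":
        if pairing is None or pairing.empty:
            raise ValueError("miRNA filtering requires a miRNA->gene pairing table")
        pairs = [
            (row.mirna, row.gene)
            for row in pairing.itertuples()
            if row.mirna in other.values.columns
        ]
    else:
        pairs = [(f, f) for f in other.values.columns]

    mapped = [(f, g) for f, g in pairs if g in mrna.values.columns]
    n_unmapped = len({f for f, _ in pairs}) - len({f for f, _ in mapped})
    unmatched = set(other.values.columns) - {f for f, _ in pairs}
    n_unmapped += len(unmatched)
    if n_unmapped:
        logger.warning("%s: %d feature(s) have no mapped mRNA gene and are excluded",
                       other.platform, n_unmapped)
    if not mapped:
        return pd.DataFrame(columns=["feature", "gene", "rho"])

    z_other = _rank_z(other.values)
    z_mrna = _rank_z(mrna.values)
    feats = [f for f, _ in mapped]
    gene_ids = [g for _, g in mapped]
    n = len(other.values)
    rho = (z_other[feats].to_numpy() * z_mrna[gene_ids].to_numpy()).sum(axis=0) / n
    return pd.DataFrame({"feature": feats, "gene": gene_ids, "rho": rho})


def filter_features(rho_table: pd.DataFrame, platform: str,
                    config: IntegrationConfig) -> pd.DataFrame:
    """Retention decisions for one platform from its Spearman table.

    A feature is retained iff its best-matching |rho| (over mapped genes,
    restricted to the expected sign under the "signed" policy) reaches
    the platform cutoff. Deterministic: best match is the max |rho|, ties
    broken by gene id.

    Returns a DataFrame indexed by feature with columns ``best_rho``,
    ``best_gene``, ``retained``.
    """
    cutoff = config.cutoff_for(platform)
    if rho_table.empty:
        return pd.DataFrame(columns=["best_rho", "best_gene", "retained"])
    tab = rho_table.copy()
    if config.sign_policy == "signed":
        sign = EXPECTED_SIGN[platform]
        tab = tab[np.sign(tab["rho"]) == sign]
        if tab.empty:
            return pd.DataFrame(
                {"best_rho": np.nan, "best_gene": "", "retained": False},
                index=pd.Index(sorted(rho_table["feature"].unique()), name="feature"),
            )
    tab = tab.assign(abs_rho=tab["rho"].abs()).sort_values(
        ["feature", "abs_rho", "gene"], ascending=[True, False, True]
    )
    best = tab.groupby("feature", sort=True).first()
    out = pd.DataFrame(
        {
            "best_rho": best["rho"],
            "best_gene": best["gene"],
            "retained": best["abs_rho"] >= cutoff,
        }
    )
    missing = sorted(set(rho_table["feature"]) - set(out.index))
    if missing:
        out = pd.concat(
            [out, pd.DataFrame({"best_rho": np.nan, "best_gene": "", "retained": False},
                               index=pd.Index(missing, name="feature"))]
        ).sort_index()
    out.index.name = "feature"
    return out


def _impute(df: pd.DataFrame, train_mask: np.ndarray, max_missing: float):
    frac = df.loc[train_mask].isna().mean()
    keep = frac <= max_missing
    if not keep.all():
        logger.warning("dropping %d feature(s) with >%d%% missing on training data",
                       int((~keep).sum()), int(max_missing * 100))
    df = df.loc[:, keep]
    medians = df.loc[train_mask].median()
    return df.fillna(medians)


def assemble_integrated(platforms: dict, retained: dict, outcomes,
                        train_mask, config: IntegrationConfig | None = None,
                        retention_report: pd.DataFrame | None = None) -> IntegratedDataset:
    """Concatenate retained features from all platforms, platform-tagged.

    ``retained`` maps platform name to the list of retained feature ids
    (mRNA may be omitted: it passes through unfiltered). Standardization
    parameters and imputation medians are computed on training samples
    only.
    """
    config = config or IntegrationConfig()
    sample_index = None
    for platform, fm in platforms.items():
        idx = fm.values.index
        if sample_index is None:
            sample_index = idx
        elif not idx.equals(sample_index):
            offending = sorted(set(idx).symmetric_difference(sample_index))
            raise ValueError(f"sample-axis mismatch on {platform}: {offending[:10]}")
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape[0] != len(sample_index):
        raise ValueError("train mask length does not match the sample axis")

    pieces = []
    for platform, fm in platforms.items():
        if platform == "mRNA":
            cols = list(fm.values.columns)
        else:
            cols = [c for c in retained.get(platform, []) if c in fm.values.columns]
        if not cols:
            continue
        block = fm.values[cols].copy()
        block.columns = pd.MultiIndex.from_product(
            [[platform], cols], names=["platform", "feature"]
        )
        pieces.append(block)
    if not pieces:
        raise ValueError("no features retained on any platform")
    combined = pd.concat(pieces, axis=1)
    combined = _impute(combined, train_mask, config.max_missing)
    if not np.all(np.isfinite(combined.to_numpy())):
        raise ValueError("non-finite values remain after imputation")

    train_mean = combined.loc[train_mask].mean()
    train_std = combined.loc[train_mask].std(ddof=0)
    report = retention_report if retention_report is not None else pd.DataFrame(
        columns=["platform", "feature", "best_rho", "retained"]
    )
    return IntegratedDataset(
        features=combined,
        outcomes=outcomes,
        train=train_mask,
        train_mean=train_mean,
        train_std=train_std,
        retention=report,
    )


class SpearmanIntegrator:
    """Fit/transform-style wrapper around the Spearman filtering step.

    ``fit`` learns retention decisions from training samples only;
    ``transform`` assembles the combined matrix for any sample set. Not a
    strict scikit-learn transformer (the input is a dict of platform
    matrices rather than a single 2-d array), but it follows the same
    fitted-attribute conventions.
    """

    def __init__(self, config: IntegrationConfig | None = None):
        self.config = config or IntegrationConfig()

    def fit(self, platforms: dict, pairing: pd.DataFrame | None = None,
            train_mask=None):
        if "mRNA" not in platforms:
            raise ValueError("integration requires an mRNA platform")
        n = len(platforms["mRNA"].values)
        mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, bool)
        mrna_train = FeatureMatrix(platforms["mRNA"].values.loc[mask], "mRNA")
        self.retained_ = {"mRNA": list(platforms["mRNA"].values.columns)}
        reports = []
        for platform, fm in platforms.items():
            if platform == "mRNA":
                continue
            fm_train = FeatureMatrix(fm.values.loc[mask], platform)
            rho = spearman_pairs(mrna_train, fm_train,
                                 pairing if platform == "miRNA" else None)
            decisions = filter_features(rho, platform, self.config)
            self.retained_[platform] = sorted(decisions.index[decisions["retained"]])
            rep = decisions.reset_index().assign(platform=platform)
            reports.append(rep)
        self.retention_report_ = (
            pd.concat(reports, ignore_index=True)
            if reports
            else pd.DataFrame(columns=["feature", "best_rho", "best_gene",
                                       "retained", "platform"])
        )
        self.train_mask_ = mask
        return self

    def transform(self, platforms: dict, outcomes, train_mask=None) -> IntegratedDataset:
        mask = self.train_mask_ if train_mask is None else np.asarray(train_mask, bool)
        return assemble_integrated(
            platforms, self.retained_, outcomes, mask, self.config,
            retention_report=self.retention_report_,
        )

    def fit_transform(self, platforms: dict, outcomes,
                      pairing: pd.DataFrame | None = None,
                      train_mask=None) -> IntegratedDataset:
        return self.fit(platforms, pairing, train_mask).transform(
            platforms, outcomes, train_mask
        )
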