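"""Uniform method invocation and the shared result container.

The central objects follow the model/results convention of statistical
modelling libraries: :class:`PathwayAnalysis` holds the data (expression,
two-level groups, pathway collection) and its ``fit(method=...)`` runs one
of the seven topology-based methods through the shared preprocessing
pipeline, returning a :class:`MethodResultSet` with per-pathway statistics,
permutation/bootstrap p-values, BH-adjusted p-values, per-gene scores where
the method provides them, and the full run metadata.

Count data is normalized (TMM by default, median-of-ratios selectable),
log-transformed and tested with the moderated t; already-normalized data
skips that step; a precomputed differential-expression table may be
supplied directly for SPIA and PRS.
"""

from __future__ import annotations

import logging
import sys
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import multivariable as mv
from . import univariable as uv
from .pathway import PathwayCollection, convert_identifiers
from .preprocess import (
    ExpressionMatrix,
    GroupLabels,
    median_ratio_factors,
    moderated_t,
    normalize_log,
    select_deg,
    tmm_factors,
)

__all__ = ["MethodResultSet", "PathwayAnalysis", "run_method", "adjust_bh", "summarize"]

METHODS = ("spia", "prs", "pwea", "tappa", "degraph", "topologygsa", "clipper")
DE_TABLE_METHODS = ("spia", "prs")

log = logging.getLogger("pathtopo")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.WARNING)


def adjust_bh(p: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MethodResultSet:
    """Per-pathway results of one method, ordered by ascending p-value.

    ``table`` has one row per pathway (name, method statistics, p, adj_p,
    status); ``gene_scores`` maps pathway name to the method's per-gene
    score vector where one exists; ``metadata`` records every option that
    influenced the run.
    """

    method: str
    table: pd.DataFrame
    gene_scores: dict[str, pd.Series] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("pathway", "p", "status"):
            if col not in t.columns:
                t[col] = pd.Series(dtype=float if col == "p" else object)
        if "adj_p" not in t.columns:
            ok = t["p"].notna()
            t["adj_p"] = np.nan
            if ok.any():
                t.loc[ok, "adj_p"] = adjust_bh(t.loc[ok, "p"].to_numpy())
        t = t.sort_values(["p", "pathway"], kind="stable", na_position="last")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(1, "method", self.method)
        return df

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def rank_of(self, pathway: str) -> int:
        """1-based rank of *pathway* by ascending p (ties by name)."""
        pos = self.table.index[self.table["pathway"] == pathway]
        if len(pos) == 0:
            raise KeyError(pathway)
        return int(pos[0]) + 1

    def summary(self, top_n: int = 10) -> str:
        return summarize(self, top_n)


def summarize(result: MethodResultSet, top_n: int = 10) -> str:
    """Plain-text table of the top pathways by ascending p-value."""
    df = result.top(top_n)
    cols = [c for c in df.columns if c not in ("pathway",)]
    header = f"method: {result.method}   pathways: {len(result)}"
    body = df.to_string(index=False, float_format=lambda v: f"{v:.4g}")
    if top_n == 0:
        body = "  ".join(["pathway"] + cols)
    return header + "\n" + body + "\n"


class PathwayAnalysis:
    """Topology-based pathway analysis of a two-condition experiment.

    Parameters
    ----------
    expression:
        ExpressionMatrix (kind "counts" or "normalized"), or a
        DifferentialExpressionTable DataFrame (columns logFC, t, p, adj_p)
        with ``data_kind="de-table"`` for SPIA/PRS.
    groups:
        Two-level GroupLabels (required unless a DE table is supplied).
    pathways:
        PathwayCollection to score.
    """

    def __init__(
        self,
        expression: ExpressionMatrix | pd.DataFrame,
        groups: GroupLabels | None,
        pathways: PathwayCollection,
        data_kind: str | None = None,
        id_mapping: dict | None = None,
    ) -> None:
        if len(pathways) == 0:
            raise ValueError("empty pathway collection")
        if isinstance(expression, ExpressionMatrix):
            data_kind = data_kind or expression.kind
            if data_kind != expression.kind:
                raise ValueError("data_kind does not match the expression matrix")
        elif data_kind != "de-table":
            raise ValueError("a raw DataFrame requires data_kind='de-table'")
        if data_kind not in ("counts", "normalized", "de-table"):
            raise ValueError(f"data_kind must be counts|normalized|de-table, got {data_kind!r}")
        if data_kind != "de-table" and groups is None:
            raise ValueError("groups are required unless a DE table is supplied")
        if id_mapping:
            pathways = PathwayCollection.from_pathways(
                convert_identifiers(p, id_mapping) for p in pathways
            )
        self.expression = expression
        self.groups = groups
        self.pathways = pathways
        self.data_kind = data_kind
        self._cache: dict[tuple, Any] = {}

    # -- preprocessing ------------------------------------------------------

    def _normalized(self, norm: str, prior: float) -> ExpressionMatrix:
        key = ("norm", norm, prior)
        if key not in self._cache:
            if self.data_kind == "counts":
                factors = (
                    tmm_factors(self.expression)
                    if norm == "tmm"
                    else median_ratio_factors(self.expression)
                )
                log.info("normalized counts with %s factors", norm)
                self._cache[key] = normalize_log(self.expression, factors, prior)
            elif self.data_kind == "normalized":
                self._cache[key] = self.expression
            else:
                raise ValueError("no expression matrix available from a DE table")
        return self._cache[key]

    def _de_table(self, norm: str, prior: float) -> pd.DataFrame:
        key = ("de", norm, prior)
        if key not in self._cache:
            if self.data_kind == "de-table":
                self._cache[key] = self.expression
            else:
                self._cache[key] = moderated_t(self._normalized(norm, prior), self.groups)
        return self._cache[key]

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        method: str,
        norm: str = "tmm",
        prior: float = 0.5,
        p_threshold: float = 0.05,
        lfc_threshold: float = 2.0,
        nperm: int = 1000,
        nboot: int = 2000,
        seed: int | None = None,
        orient_mode: str = "both",
        k: int | None = None,
        signed: bool = False,
        test: str = "mean",
        shrinkage: float | None = None,
        threads: int = 1,
    ) -> MethodResultSet:
        """Run one method over every pathway and collect a MethodResultSet.

        Per-pathway failures downgrade to status flags; they never abort
        the run. All randomness is derived from ``seed`` by stable hashing
        of (seed, pathway name, draw index), so the thread count cannot
        change the results.
        """
        method = method.lower()
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        if norm not in ("tmm", "medianratio"):
            raise ValueError(f"norm must be 'tmm' or 'medianratio', got {norm!r}")
        if self.data_kind == "de-table" and method not in DE_TABLE_METHODS:
            raise ValueError(
                f"a differential-expression table can only drive {DE_TABLE_METHODS}, "
                f"not {method!r}"
            )
        metadata = {
            "method": method,
            "data_kind": self.data_kind,
            "normalization": norm if self.data_kind == "counts" else "none",
            "log_transform": "prior-count log-CPM" if self.data_kind == "counts" else "none",
            "de_engine": "moderated-t" if self.data_kind != "de-table" else "user-supplied",
            "p_threshold": p_threshold,
            "lfc_threshold": lfc_threshold,
            "nperm": nperm,
            "nboot": nboot,
            "seed": seed,
            "orient_mode": orient_mode,
            "test": test,
            "committed_formulas": [
                "prs-score", "pwea-tif-exp(rho/d)", "tappa-zscore-pci",
                "clipper-path-mean-neglog10p",
            ],
        }

        if method in ("spia", "prs"):
            de = self._de_table(norm, prior)
            deg = select_deg(de, p_threshold, lfc_threshold)
            all_genes = list(de.index)
            if method == "spia":
                fn = lambda pw: uv.spia(pw, de, deg, all_genes, nboot=nboot,
                                        seed=seed, orient_mode=orient_mode)
            else:
                fn = lambda pw: uv.prs(pw, de, deg, all_genes, nperm=nperm,
                                       seed=seed, orient_mode=orient_mode)
        elif method == "pwea":
            expr = self._normalized(norm, prior)
            values = expr.values.to_numpy(dtype=float)
            m1, m2 = self.groups.masks(expr.samples)
            perm_t = uv.pwea_permuted_t(values, m1, m2, nperm, seed)
            fn = lambda pw: uv.pwea(pw, expr, self.groups, nperm=nperm, seed=seed,
                                    perm_t=perm_t)
        elif method == "tappa":
            expr = self._normalized(norm, prior)
            fn = lambda pw: uv.tappa(pw, expr, self.groups)
        elif method == "degraph":
            expr = self._normalized(norm, prior)
            fn = lambda pw: mv.degraph(pw, expr, self.groups, k=k, signed=signed)
        elif method == "topologygsa":
            expr = self._normalized(norm, prior)
            fn = lambda pw: mv.topology_gsa(pw, expr, self.groups, test=test,
                                            nperm=nperm, seed=seed)
        else:  # clipper
            expr = self._normalized(norm, prior)
            fn = lambda pw: mv.clipper(pw, expr, self.groups, test=test,
                                       nperm=nperm, seed=seed, shrinkage=shrinkage)

        def safe(pw):
            try:
                return fn(pw)
            except Exception as exc:  # downgrade to a status flag
                log.warning("pathway %s failed: %s", pw.id, exc)
                return ("failed", pw.id, str(exc))

        pws = list(self.pathways)
        if threads > 1:
            with ThreadPoolExecutor(max_workers=threads) as ex:
                raw = list(ex.map(safe, pws))
        else:
            raw = [safe(pw) for pw in pws]

        rows: list[dict] = []
        gene_scores: dict[str, pd.Series] = {}
        extras: dict[str, Any] = {}
        for pw, res in zip(pws, raw):
            if isinstance(res, tuple):
                rows.append({"pathway": pw.id, "p": np.nan, "status": "failed"})
                continue
            row = {"pathway": pw.id, "p": res.p, "status": res.status}
            if isinstance(res, uv.SpiaResult):
                row.update(n_genes=res.n_genes, n_de=res.n_de, t_a=res.t_a,
                           p_nde=res.p_nde, p_pert=res.p_pert)
                if len(res.acc):
                    gene_scores[pw.id] = res.acc
            elif isinstance(res, uv.PrsResult):
                row.update(raw_score=res.raw, null_mean=res.null_mean,
                           null_sd=res.null_sd, z=res.z)
                if len(res.contributions):
                    gene_scores[pw.id] = res.contributions
            elif isinstance(res, uv.PweaResult):
                row.update(es=res.es)
                if len(res.tif):
                    gene_scores[pw.id] = res.tif
            elif isinstance(res, uv.TappaResult):
                row.update(u=res.u)
                if len(res.pci):
                    extras[pw.id] = {"pci": res.pci}
            elif isinstance(res, mv.MultivarResult):
                row.update(p_mean=res.p_mean, p_var=res.p_var)
                if res.k is not None:
                    row["k"] = res.k
                if res.cliques:
                    extras[pw.id] = {
                        "cliques": res.cliques,
                        "best_path": res.best_path,
                        "best_path_score": res.best_path_score,
                        "junction_tree": res.junction_tree,
                    }
            rows.append(row)
        skipped = [r["pathway"] for r in rows if r["status"] != "ok"]
        if skipped:
            log.warning("%s: %d pathway(s) skipped or degenerate: %s",
                        method, len(skipped), ", ".join(skipped[:10]))
        table = pd.DataFrame(rows)
        return MethodResultSet(method, table, gene_scores, extras, metadata)


def run_method(
    method: str,
    data: ExpressionMatrix | pd.DataFrame,
    groups: GroupLabels | None,
    pathways: PathwayCollection,
    data_kind: str | None = None,
    id_mapping: dict | None = None,
    **options,
) -> MethodResultSet:
    """Functional one-call interface: build a PathwayAnalysis and fit it."""
    model = PathwayAnalysis(data, groups, pathways, data_kind=data_kind,
                            id_mapping=id_mapping)
    return model.fit(method, **options)
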