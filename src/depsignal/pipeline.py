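"""End-to-end orchestration: preprocessing, feature extraction, topic
modelling, screening, similarity, prediction and participation trends,
with every intermediate artifact written to a run directory.

A single global seed fans out deterministically to per-stage seeds, so two
runs with the same configuration and inputs produce identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np

from . import preprocess as pp
from . import features as ft
from . import lda as topic
from . import similarity as sim
from . import predict as pr
from .synthetic import SyntheticSpec, generate_corpus, generate_lexicons

log = logging.getLogger(__name__)

STAGES = ("preprocess", "features", "lda", "screen", "similarity", "predict", "trend")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (global_seed * 1009 + STAGES.index(stage) if stage in STAGES
            else global_seed * 1009 + 97) % (2**31)


@dataclass
class RunConfig:
    """Full-run configuration; defaults follow the package's standard
    analysis settings (50 topics, symmetric priors 0.01, top-15 words,
    screen threshold 2, 10-fold elastic net)."""

    corpus_path: str | None = None
    lexicon_dir: str | None = None
    output_dir: str = "depsignal_run"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)   # used when corpus_path is None
    filter: dict = field(default_factory=dict)      # FilterConfig overrides
    n_topics: int = 50
    weekly_topics: int | None = None                # per-week model size; default n_topics
    alpha: float = 0.01
    beta: float = 0.01
    n_iter: int = 200
    screen_m: int = 2
    engage_threshold: float = 0.2
    retain: int = 10
    epsilon: float = 1e-6
    n_permutations: int = 2000
    min_df: int = 2
    regression: dict = field(default_factory=dict)
    classifiers: tuple = ("svm", "lr", "rf")
    family_combos: tuple = (("liwc",), ("liwc", "lda"),
                            ("liwc", "bigram", "lda"),
                            ("liwc", "plus", "bigram", "lda"))

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("classifiers", "family_combos"):
            if key in raw:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x for x in raw[key]) \
                    if key == "family_combos" else tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise FileNotFoundError(f"corpus_path {self.corpus_path} not readable")
        if self.lexicon_dir is not None and not Path(self.lexicon_dir).is_dir():
            raise FileNotFoundError(f"lexicon_dir {self.lexicon_dir} not readable")
        if self.corpus_path is None and self.lexicon_dir is not None:
            raise ValueError("synthetic corpus requires generated lexicons (leave lexicon_dir unset)")


def _month_label(dt) -> str:
    return f"{dt.year:04d}-{dt.month:02d}"


def participation_trend(weekly_corpora, weekly_models, weekly_screens,
                        cfg: RunConfig, filter_cfg: pp.FilterConfig) -> dict:
    """Weekly distinct-user counts of depression-topic participants and the
    monthly percentage of all collected users they represent."""
    weekly_counts = []
    month_participants: dict[str, set] = {}
    month_users: dict[str, set] = {}
    for i, (corpus, model, screen) in enumerate(zip(weekly_corpora, weekly_models,
                                                    weekly_screens)):
        month = _month_label(pp.week_start(filter_cfg, i))
        users_all = {t.user_id for t in corpus}
        month_users.setdefault(month, set()).update(users_all)
        if model is None:
            weekly_counts.append(0)
            continue
        group = topic.experimental_group(
            corpus, model, screen,
            engage_threshold=cfg.engage_threshold,
            min_tweets=1,  # weekly counts: participation within the week
        )
        weekly_counts.append(len(group))
        month_participants.setdefault(month, set()).update(group)
    monthly_pct = {
        m: 100.0 * len(month_participants.get(m, set())) / len(users)
        for m, users in month_users.items() if users
    }
    return {"weekly_counts": weekly_counts, "monthly_pct": monthly_pct}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage, writing artifacts and a manifest to the output
    directory; returns the run directory path."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    current = "setup"
    try:
        # -- inputs ---------------------------------------------------------
        if cfg.corpus_path is None:
            spec = SyntheticSpec(**{"seed": cfg.seed, **cfg.synthetic})
            tweets, truth = generate_corpus(spec)
            bundle = generate_lexicons(spec)
            bundle.save(out / "lexicons")
            pp.write_jsonl(tweets, out / "corpus_raw.jsonl")
            manifest["synthetic"] = {
                k: v for k, v in dataclasses.asdict(spec).items()
                if isinstance(v, (int, float, str, bool))
            }
        else:
            tweets = pp.read_jsonl(cfg.corpus_path)
            bundle = ft.LexiconBundle.load(cfg.lexicon_dir)

        fkw = dict(cfg.filter)
        if "period_start" not in fkw:
            fkw["period_start"] = min(t.created_at for t in tweets)
        if "period_end" not in fkw:
            fkw["period_end"] = max(t.created_at for t in tweets) + timedelta(seconds=1)
        # synthetic vocabulary must not collide with the packaged stopword list
        filter_cfg = pp.FilterConfig(**fkw)

        # -- preprocess -----------------------------------------------------
        current = "preprocess"
        clean, report = pp.preprocess_corpus(tweets, filter_cfg)
        pp.write_jsonl(clean, out / "corpus_clean.jsonl")
        (out / "prep_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["stages"]["preprocess"] = report
        weeks = pp.slice_weekly(clean, filter_cfg)

        # -- features -------------------------------------------------------
        current = "features"
        bigram_fm, _ = ft.tfidf_bigrams(clean, min_df=cfg.min_df)
        liwc_fm = ft.liwc_matrix(clean, bundle)
        plus_fm = ft.plus_matrix(clean, bundle)
        manifest["stages"]["features"] = {
            "documents": len(clean),
            "bigram_columns": len(bigram_fm.column_names),
        }

        # -- global topic model --------------------------------------------
        current = "lda"
        model = topic.fit_lda(clean, K=cfg.n_topics, alpha=cfg.alpha, beta=cfg.beta,
                              n_iter=cfg.n_iter, seed=stage_seed(cfg.seed, "lda"))
        lda_fm = topic.topic_features(model, clean)
        doc_fm = ft.assemble([liwc_fm, plus_fm, bigram_fm, lda_fm])
        doc_fm.save_csv(out / "features_documents.csv")
        manifest["stages"]["lda"] = {"K": cfg.n_topics, "n_iter": cfg.n_iter,
                                     "vocabulary": model.V}

        # -- screening ------------------------------------------------------
        current = "screen"
        screen = topic.screen_all(model, bundle, m=cfg.screen_m)
        with open(out / "topics_top_words.tsv", "w") as fh:
            fh.write("topic\tindicative\twords\n")
            for s in screen:
                words = " ".join(w for w, _ in s.top_words)
                fh.write(f"{s.topic_id}\t{int(s.indicative)}\t{words}\n")
        (out / "screen.json").write_text(json.dumps(
            [{"topic": s.topic_id, "indicative": s.indicative,
              "matched": sorted(s.matched_depression_words)} for s in screen],
            indent=2))
        n_ind = sum(s.indicative for s in screen)
        manifest["stages"]["screen"] = {"indicative_topics": n_ind}

        # -- weekly models, similarity, trend -------------------------------
        current = "similarity"
        kw = cfg.weekly_topics or cfg.n_topics
        weekly_models, weekly_screens, weekly_summaries, weekly_rho = [], [], [], []
        months = []
        for i, wk in enumerate(weeks):
            months.append(_month_label(pp.week_start(filter_cfg, i)))
            if len(wk) < max(2, kw):
                weekly_models.append(None)
                weekly_screens.append([])
                weekly_summaries.append(sim.PeriodSummary(f"week{i}", 0, 0,
                                                          float("nan"), float("nan"),
                                                          float("nan")))
                weekly_rho.append(None)
                continue
            wmodel = topic.fit_lda(wk, K=kw, alpha=cfg.alpha, beta=cfg.beta,
                                   n_iter=cfg.n_iter,
                                   seed=(stage_seed(cfg.seed, "similarity") + i) % 2**31)
            wscreen = topic.screen_all(wmodel, bundle, m=cfg.screen_m)
            pairs, summary = sim.period_similarity(wscreen, bundle, f"week{i}",
                                                   retain=cfg.retain, epsilon=cfg.epsilon)
            rho = None
            if len(pairs) >= 3:
                res = sim.cross_metric_spearman(
                    pairs, n_permutations=cfg.n_permutations,
                    seed=(stage_seed(cfg.seed, "similarity") + 1000 + i) % 2**31)
                if not res.constant_input:
                    rho = {"rho": res.rho, "p": res.p_value}
            weekly_models.append(wmodel)
            weekly_screens.append(wscreen)
            weekly_summaries.append(summary)
            weekly_rho.append(rho)
        trend_sim = sim.monthly_trend(weekly_summaries, months)
        sim_report = {
            "weekly": [dataclasses.asdict(s) for s in weekly_summaries],
            "weekly_spearman": weekly_rho,
            "monthly": trend_sim,
        }
        (out / "similarity.json").write_text(json.dumps(sim_report, indent=2,
                                                        sort_keys=True, allow_nan=True))
        manifest["stages"]["similarity"] = {"weeks": len(weeks)}

        # -- prediction -----------------------------------------------------
        current = "predict"
        umap = ft.user_map_of(clean)
        user_fm = ft.aggregate_by_user(doc_fm, umap)
        y = pr.depression_signal_score(user_fm)
        reg_cfg = pr.RegressionConfig(**{"seed": stage_seed(cfg.seed, "predict"),
                                         **cfg.regression})
        reg_rows = []
        if len(np.unique(y)) > 1 and len(y) >= reg_cfg.n_folds:
            for combo in cfg.family_combos:
                X = ft.assemble([user_fm.family(f) for f in combo])
                res = pr.elasticnet_cv(X, y, reg_cfg, "+".join(combo))
                reg_rows.append({"feature_set": res.feature_set_name,
                                 "pearson_r": res.pearson_r, "p": res.p_value})
        with open(out / "predict_regression.tsv", "w") as fh:
            fh.write("feature_set\tpearson_r\tp\n")
            for r in reg_rows:
                fh.write(f"{r['feature_set']}\t{r['pearson_r']}\t{r['p']}\n")

        # weekly user-level matrices for temporal classification
        weekly_data = []
        _, bigram_stats = ft.tfidf_bigrams(clean, min_df=cfg.min_df)
        for i, wk in enumerate(weeks):
            if not wk:
                continue
            wl = ft.liwc_matrix(wk, bundle)
            wp = ft.plus_matrix(wk, bundle)
            wlda = topic.topic_features(model, wk)
            # weekly bigram vocabularies differ; project onto the global fit
            wb_global, _ = ft.tfidf_bigrams(wk, min_df=cfg.min_df, stats=bigram_stats)
            wfm = ft.assemble([wl, wp, wb_global, wlda])
            ufm = ft.aggregate_by_user(wfm, ft.user_map_of(wk))
            ufm = ft.FeatureMatrix([f"{u}@w{i}" for u in ufm.row_ids],
                                   ufm.column_names, ufm.values, ufm.family_slices)
            scores = pr.depression_signal_score(ufm)
            weekly_data.append((ufm, scores))
        clf_rows = []
        if len(weekly_data) >= 2:
            thr = float(np.median(np.concatenate([s for _, s in weekly_data[:-1]])))
            labeled = [(fm, (s >= thr).astype(int)) for fm, s in weekly_data]
            ok = all(len(np.unique(lbl)) == 2 for _, lbl in labeled[:-1])
            if ok:
                cfgs = [pr.ClassifierConfig(kind=k, seed=stage_seed(cfg.seed, "predict"))
                        for k in cfg.classifiers]
                df = pr.feature_ablation(labeled, cfg.family_combos, cfgs)
                df.to_csv(out / "predict_classification.tsv", sep="\t", index=False)
                clf_rows = df.to_dict("records")
        manifest["stages"]["predict"] = {"regression": reg_rows,
                                         "classification": clf_rows}

        # -- participation trend -------------------------------------------
        current = "trend"
        trend = participation_trend(weeks, weekly_models, weekly_screens,
                                    cfg, filter_cfg)
        (out / "trend.json").write_text(json.dumps(trend, indent=2, sort_keys=True))
        manifest["stages"]["trend"] = {"weeks": len(trend["weekly_counts"])}
    except Exception as exc:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return out
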