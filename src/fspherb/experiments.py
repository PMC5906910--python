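"""The two simulation campaigns and their statistics.

The evaluation campaign grows uninfested stands at several densities and
summarises biomass, seed yield, branching, height and the main-stem
leaf-length profile.  The herbivory campaign runs the full factorial of
density x herbivore feeding preference x spatial distribution pattern x
herbivore number, and tests treatment effects with a sequential
(Type-I) ANOVA on a linear regression of yield on herbivore number and
feeding preference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import RunConfig, Treatment, run


@dataclass
class AnovaResult:
    table: pd.DataFrame           # terms x (df, sum_sq, F, PR(>F))
    coefficients: pd.DataFrame

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def _sub_seeds(base_seed: int, k: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence([int(base_seed), int(k)])
    a, b, c = ss.generate_state(3)
    return int(a % 2**31), int(b % 2**31), int(c % 2**31)


def _run_once(base: RunConfig, density: float, n_plants: int, seed: int,
              rep: int, treatment: Treatment | None = None):
    sp, sl, sh = _sub_seeds(seed, rep)
    cfg = replace(base, density=density, n_plants=n_plants,
                  seed_plants=sp, seed_light=sl, seed_herbivores=sh,
                  treatment=treatment or Treatment())
    return run(cfg)


DENSITY_PLANTS = {1.0: 4, 4.0: 4, 25.0: 16}


def evaluation_campaign(base: RunConfig | None = None,
                        densities=(1.0, 4.0, 25.0),
                        n_replicates: int = 10,
                        seed: int = 1) -> dict:
    """Uninfested stands at several densities, ``n_replicates`` seeds each.

    Returns per-run plant tables, a per-density summary (mean and standard
    error over replicate-plot means), daily LAI / R:FR series and the
    main-stem leaf-length-by-rank profile.
    """
    base = base or RunConfig()
    plants, daily, profiles = [], [], []
    for dens in densities:
        n_pl = DENSITY_PLANTS.get(float(dens), 16)
        for rep in range(n_replicates):
            res = _run_once(base, dens, n_pl, seed, rep)
            df = res.plants.assign(density=dens, replicate=rep)
            plants.append(df)
            daily.append(res.daily.assign(density=dens, replicate=rep))
            profiles.append(res.leaf_profile.assign(density=dens, replicate=rep))
    plants = pd.concat(plants, ignore_index=True)
    daily = pd.concat(daily, ignore_index=True)
    profiles = pd.concat(profiles, ignore_index=True)
    # plot means first, then mean +/- s.e. over replicates
    per_rep = plants.groupby(["density", "replicate"])[
        ["biomass", "yield", "height", "branches", "leaf_area"]].mean()
    summary = per_rep.groupby("density").agg(["mean", "sem"])
    profile_summary = (profiles.groupby(["density", "rank"])["leaf_length"]
                       .agg(["mean", "sem"]).reset_index())
    return {"plants": plants, "daily": daily, "profiles": profiles,
            "summary": summary, "profile_summary": profile_summary}


def herbivory_campaign(base: RunConfig | None = None,
                       densities=(1.0, 25.0),
                       patterns=("homogeneous", "heterogeneous", "alternating"),
                       herbivore_numbers=(5, 10, 15, 20),
                       preferences=(0.2, 0.8),
                       n_replicates: int = 5,
                       seed: int = 1) -> dict:
    """Full factorial herbivory treatments with per-panel yield ANOVAs.

    Patterns ``homogeneous`` and ``heterogeneous`` are crossed with the two
    feeding preferences (h); ``alternating`` contains both preferences by
    construction.  Per (density, pattern) panel, plot-level class means are
    regressed on herbivore number and preference class.
    """
    base = base or RunConfig()
    rows = []
    for dens in densities:
        n_pl = DENSITY_PLANTS.get(float(dens), 16)
        for pattern in patterns:
            h_list = [None] if pattern == "alternating" else list(preferences)
            for h in h_list:
                for n_herb in herbivore_numbers:
                    for rep in range(n_replicates):
                        tr = Treatment(pattern=pattern, n_per_plant=int(n_herb),
                                       h=h if h is not None else 0.8)
                        # common random numbers: replicate r shares its seeds
                        # across every treatment cell (a paired design), so
                        # treatment contrasts are not confounded with the
                        # plot-to-plot variation of the plant draws
                        res = _run_once(base, dens, n_pl, seed, rep, tr)
                        df = res.plants
                        for cls, grp in df.groupby("class"):
                            rows.append({
                                "density": dens, "pattern": pattern,
                                "h": (h if h is not None else
                                      (0.8 if cls == "young-feeder" else 0.2)),
                                "class": cls, "n_herbivores": int(n_herb),
                                "replicate": rep,
                                "yield": grp["yield"].mean(),
                                "biomass": grp["biomass"].mean(),
                                "damage": grp["damage"].mean(),
                                "branches": grp["branches"].mean(),
                            })
    table = pd.DataFrame(rows)
    anovas = {}
    for (dens, pattern), panel in table.groupby(["density", "pattern"]):
        infested = panel[panel["class"] != "clean"]
        if infested["class"].nunique() > 1 or pattern == "alternating":
            try:
                anovas[(dens, pattern)] = linear_anova(
                    infested, "yield", "n_herbivores", "class")
            except ValueError:
                pass
    return {"table": table, "anovas": anovas}


def linear_anova(table: pd.DataFrame, outcome: str, n_col: str,
                 class_col: str | None = None) -> AnovaResult:
    """OLS of ``outcome`` on herbivore number (and preference class) with
    sequential (Type-I) F tests; exact on balanced designs."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    # formula-safe column names (treatment columns may shadow keywords)
    df = table.rename(columns={outcome: "_y", n_col: "_n"}).copy()
    if df["_y"].size < 3:
        raise ValueError("too few observations for an ANOVA")
    if class_col is not None and df[class_col].nunique() > 1:
        df = df.rename(columns={class_col: "_cls"})
        formula = "_y ~ _n * C(_cls)"
    else:
        formula = "_y ~ _n"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design (aliased term)")
    if np.allclose(df["_y"].var(ddof=1), 0.0):
        # constant outcome: all effects vanish
        rename = {"_n": n_col, "C(_cls)": f"C({class_col})",
                  "_n:C(_cls)": f"{n_col}:C({class_col})"}
        terms = [rename.get(t, t)
                 for t in model.model.data.design_info.term_names
                 if t != "Intercept"]
        tab = pd.DataFrame({"df": np.nan, "sum_sq": 0.0, "F": 0.0,
                            "PR(>F)": 1.0}, index=terms)
        return AnovaResult(tab, model.params.to_frame("coef"))
    tab = anova_lm(model, typ=1)
    rename = {"_n": n_col, "C(_cls)": f"C({class_col})",
              "_n:C(_cls)": f"{n_col}:C({class_col})"}
    tab = tab.rename(index=rename)
    return AnovaResult(tab, model.params.to_frame("coef"))
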