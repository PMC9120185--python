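"""Synthetic multi-country Likert survey generator.

Responses follow a latent-trait ordinal model: each respondent draws a
latent trust value t ~ Normal(country mean, latent_sd); each item observes
t plus independent item noise and discretizes it through fixed cut-points,
so cross-item correlations are driven by the shared latent trait.

The *decoupling* knob d emulates the empirical isolation of strong-trust
attitudes by resolving mixed profiles: with probability d a respondent's
profile is polarized — if the latent trait is above the top cut-point the
respondent answers the top level ("strongly agree") on every item, and
otherwise any top-level answers are re-drawn uniformly from the interior
levels.  Raising d removes the mixed strong/weak profiles that couple
top-level answers to everything else, which raises the attitude-isolation
statistic measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_core import Item, SurveyDataset

__all__ = ["GeneratorParams", "default_items", "generate_dataset", "generate_isolation_gradient"]

# Cut-points chosen for equal level occupancy at the default scale
# (latent_sd = item_noise_sd = 1, country mean 0): quintiles / quartiles of
# Normal(0, sqrt(2)).
_CUTS_5 = np.array([-1.19023, -0.35828, 0.35828, 1.19023])
_CUTS_4 = np.array([-0.95387, 0.0, 0.95387])


def default_items(n_extra_items: int = 4) -> list[Item]:
    """Three 5-level vaccine items plus 4-level trust items (science and
    institutions, alternating)."""
    items = [
        Item("vax_important", topic="vaccine", n_levels=5),
        Item("vax_safe", topic="vaccine", n_levels=5),
        Item("vax_effective", topic="vaccine", n_levels=5),
    ]
    for k in range(n_extra_items):
        topic = "science" if k % 2 == 0 else "institutions"
        items.append(Item(f"trust_{topic}_{k // 2 + 1}", topic=topic, n_levels=4))
    return items


@dataclass
class GeneratorParams:
    """Knobs of the synthetic survey generator.

    ``latent_means`` gives one country mean (a scalar is broadcast);
    ``decoupling`` likewise one value per country in [0, 1].
    """

    n_countries: int = 1
    n_per_country: int = 1000
    n_extra_items: int = 4
    latent_means: float | Sequence[float] = 0.0
    latent_sd: float = 1.0
    item_noise_sd: float = 1.0
    decoupling: float | Sequence[float] = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.n_per_country < 2:
            raise ValueError("n_per_country must be >= 2")
        if self.n_extra_items < 0:
            raise ValueError("n_extra_items must be >= 0")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be > 0")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for d in np.atleast_1d(np.asarray(self.decoupling, dtype=float)):
            if not 0.0 <= d <= 1.0:
                raise ValueError("decoupling must be in [0, 1]")

    def per_country(self, attr: str) -> np.ndarray:
        vals = np.broadcast_to(
            np.asarray(getattr(self, attr), dtype=float), (self.n_countries,)
        )
        return np.array(vals)


def _discretize(latent: np.ndarray, n_levels: int) -> np.ndarray:
    cuts = _CUTS_5 if n_levels == 5 else _CUTS_4
    return np.searchsorted(cuts, latent) + 1


def generate_dataset(params: GeneratorParams) -> SurveyDataset:
    """Draw a full multi-country survey. Deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    items = default_items(params.n_extra_items)
    means = params.per_country("latent_means")
    ds = params.per_country("decoupling")

    frames = []
    for c in range(params.n_countries):
        n = params.n_per_country
        country = f"C{c + 1:02d}"
        t = rng.normal(means[c], params.latent_sd, size=n)
        cols: dict[str, object] = {
            "respondent_id": [f"{country}_{i:05d}" for i in range(n)],
            "country": country,
        }
        # profile resolution: with prob d a respondent polarizes — a
        # latent trait above the top cut answers top everywhere, one
        # below it loses its top answers to interior levels
        polar = rng.random(n) < ds[c]
        committed = t > _CUTS_5[-1]
        for it in items:
            obs = t + rng.normal(0.0, params.item_noise_sd, size=n)
            codes = _discretize(obs, it.n_levels).astype(float)
            codes[polar & committed] = it.n_levels
            redraw = polar & ~committed & (codes == it.n_levels)
            codes[redraw] = rng.integers(2, it.n_levels, size=int(redraw.sum()))
            if params.missing_rate > 0:
                codes[rng.random(n) < params.missing_rate] = np.nan
            cols[it.item_id] = codes
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)
    return SurveyDataset(table, items)


def generate_isolation_gradient(
    base: GeneratorParams, d_values: Sequence[float]
) -> SurveyDataset:
    """Multi-country dataset with one decoupling value per country.

    Country k is generated with decoupling ``d_values[k]``; on average its
    attitude-isolation increases with d, giving a controlled gradient for
    studying isolation-dependent dynamics.
    """
    d_values = list(d_values)
    if len(d_values) != base.n_countries:
        raise ValueError(
            f"d_values has {len(d_values)} entries for {base.n_countries} countries"
        )
    params = GeneratorParams(
        n_countries=base.n_countries,
        n_per_country=base.n_per_country,
        n_extra_items=base.n_extra_items,
        latent_means=base.latent_means,
        latent_sd=base.latent_sd,
        item_noise_sd=base.item_noise_sd,
        decoupling=d_values,
        missing_rate=base.missing_rate,
        seed=base.seed,
    )
    return generate_dataset(params)
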