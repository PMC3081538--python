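"""Synthetic labeled feature tables emulating a multi-tool localization study.

The real study data — 6819 SwissProt-derived proteins (467 mitochondrial,
6352 non-mitochondrial) scored by eleven heterogeneous prediction tools — is
no longer hosted, so this module generates tables with the same statistical
structure: per-tool true/false positive rates, partial coverage (orthology
tools return no call for most proteins), correlated tools that share an
evidence basis (two of the eleven are Pfam-domain based), and continuous
score jitter on top of binary core calls.

Generation model, per protein ``i`` and tool ``t``:

* the cell is missing with probability ``1 - coverage``;
* otherwise a binary core call is drawn: 1 with probability ``tpr`` if the
  protein is mitochondrial, ``fpr`` if not.  Tools within a correlation
  group draw from a shared per-protein uniform with probability
  ``latent_strength`` instead of their own uniform, which makes their calls
  positively correlated while preserving each tool's marginal rates;
* the stored value is ``clip(call + Normal(0, noise_sd), 0, 1)``.

Everything is driven by a single seeded :class:`numpy.random.Generator`, so
one seed yields a byte-identical table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np

from .feature_table import FeatureTable


@dataclass(frozen=True)
class PredictorProfile:
    """Generative description of one prediction tool.

    ``tpr``/``fpr`` are the probabilities of a positive core call for
    mitochondrial / non-mitochondrial proteins; ``coverage`` is the
    probability the tool returns any call at all; tools sharing a
    ``correlation_group`` are driven by a common latent event; ``noise_sd``
    jitters the stored score around the binary call.  ``role`` is a free
    descriptive tag (e.g. strong / moderate / detrimental) used by packaged
    scenarios.
    """

    name: str
    tpr: float
    fpr: float
    coverage: float = 1.0
    correlation_group: str | None = None
    noise_sd: float = 0.0
    role: str | None = None

    def __post_init__(self) -> None:
        for attr in ("tpr", "fpr", "coverage"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete generative scenario: tool roster plus class sizes."""

    profiles: tuple[PredictorProfile, ...]
    n_pos: int
    n_neg: int
    latent_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(self.profiles) < 1:
            raise ValueError("a scenario needs at least one predictor profile")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 proteins per class")
        if not 0.0 <= self.latent_strength <= 1.0:
            raise ValueError("latent_strength must lie in [0, 1]")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate profile names")
        groups: dict[str, int] = {}
        for p in self.profiles:
            if p.correlation_group is not None:
                groups[p.correlation_group] = groups.get(p.correlation_group, 0) + 1
        for g, count in groups.items():
            if count < 2:
                raise ValueError(f"correlation group {g!r} references only {count} profile")

    # -- JSON round trip ------------------------------------------------

    def to_json(self) -> str:
        payload = asdict(self)
        payload["profiles"] = [asdict(p) for p in self.profiles]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str, seed: int | None = None) -> "ScenarioConfig":
        payload = json.loads(text)
        profiles = tuple(PredictorProfile(**p) for p in payload.pop("profiles"))
        if seed is not None:
            payload["seed"] = seed
        return cls(profiles=profiles, **payload)


def generate_dataset(config: ScenarioConfig) -> FeatureTable:
    """Draw a labeled feature table from a scenario.

    Rows are the ``n_pos`` mitochondrial proteins followed by the ``n_neg``
    non-mitochondrial ones (splitting shuffles anyway); ids are synthetic
    ``SYN######`` accessions.  Identical configs produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    labels = np.concatenate([
        np.ones(config.n_pos, dtype=np.int8),
        np.zeros(config.n_neg, dtype=np.int8),
    ])
    protein_ids = [f"SYN{i + 1:06d}" for i in range(n)]

    # one shared uniform per (protein, correlation group), in sorted group order
    group_names = sorted({p.correlation_group for p in config.profiles if p.correlation_group})
    group_u = {g: rng.random(n) for g in group_names}

    m = len(config.profiles)
    values = np.zeros((n, m), dtype=np.float64)
    missing = np.zeros((n, m), dtype=bool)
    for j, prof in enumerate(config.profiles):
        # draws are unconditional and in fixed order to keep the stream stable
        covered = rng.random(n) < prof.coverage
        own_u = rng.random(n)
        use_latent = rng.random(n) < config.latent_strength
        noise = rng.standard_normal(n)
        if prof.correlation_group is not None:
            u = np.where(use_latent, group_u[prof.correlation_group], own_u)
        else:
            u = own_u
        rate = np.where(labels == 1, prof.tpr, prof.fpr)
        call = (u < rate).astype(np.float64)
        values[:, j] = np.clip(call + prof.noise_sd * noise, 0.0, 1.0)
        missing[:, j] = ~covered

    return FeatureTable(
        protein_ids=protein_ids,
        labels=labels,
        tool_names=[p.name for p in config.profiles],
        values=np.where(missing, 0.0, values),
        missing_mask=missing,
    )


def _load_packaged_scenario(filename: str, seed: int) -> ScenarioConfig:
    text = resources.files("mitosweep.data").joinpath(filename).read_text(encoding="utf-8")
    return ScenarioConfig.from_json(text, seed=seed)


def paradox_scenario(seed: int = 0) -> ScenarioConfig:
    """The packaged eleven-tool scenario exhibiting the combination paradox.

    Three strong complementary tools (Pfam-domain, targeting-signal and a
    second Pfam-based genome-scale predictor — the two Pfam-based ones share
    a correlation group), four moderate tools, and four detrimental tools
    with low coverage and signal-free near-random calls (emulating distant
    orthology and coexpression evidence).  Class sizes are the study's
    467 mitochondrial / 6352 non-mitochondrial proteins.  Exact rates live
    in ``data/paradox_scenario.json``.
    """
    return _load_packaged_scenario("paradox_scenario.json", seed)


def desk_scenario(seed: int = 0) -> ScenarioConfig:
    """A scaled-down eight-tool variant of :func:`paradox_scenario`.

    Keeps the strong/moderate/detrimental architecture (3 + 2 + 3 tools) on
    a 1500-protein table (150 mitochondrial / 1350 non-mitochondrial, the
    study's ~1:9 imbalance) so the full 255-subset sweep runs in minutes.
    """
    return _load_packaged_scenario("desk_scenario.json", seed)
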