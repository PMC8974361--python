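import datetime as dt

import numpy as np
import pytest

from mediapce.records import MediaDocument
from mediapce.synthetic import GeneratorConfig, YouTubeSpec


def small_config(seed: int = 0, **kw) -> GeneratorConfig:
    """A short study: 228 media days, 200 survey days, 10 interviews/day."""
    defaults = dict(
        start_date=dt.date(2015, 1, 1),
        end_date=dt.date(2015, 8, 16),
        survey_lead_days=28,
        youtube=YouTubeSpec(start_date=dt.date(2015, 1, 1)),
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    from mediapce.study import simulate_study

    return simulate_study(small_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def longform_doc(date, p_anti=0.0, p_pro=0.0, source="newspapers", passing=True,
                 votes=None, doc_id=None):
    return MediaDocument(
        doc_id=doc_id or f"{source}-{date}-{p_anti}-{p_pro}",
        source=source,
        source_type="longform",
        date=date,
        p_anti=p_anti,
        p_pro=p_pro,
        more_than_passing=passing,
        coder_votes=votes,
    )


def tweet(date, anti=0, pro=0, doc_id=None):
    return MediaDocument(
        doc_id=doc_id or f"tw-{date}-{anti}{pro}",
        source="twitter",
        source_type="twitter",
        date=date,
        p_anti=float(anti),
        p_pro=float(pro),
    )
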