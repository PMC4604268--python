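import json

import pytest

import natfreq as nf

MAMMOGRAPHY_JSON = json.dumps(
    {
        "hypotheses": [
            {"label": "cancer", "prior": 0.01},
            {"label": "no cancer", "prior": 0.99},
        ],
        "population": 1000,
        "cues": [
            {
                "name": "mammogram",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": "cancer",
                     "distribution": {"positive": 0.80, "negative": 0.20}},
                    {"hypothesis": "no cancer",
                     "distribution": {"positive": 0.096, "negative": 0.904}},
                ],
            }
        ],
    }
)

COLON_JSON = json.dumps(
    {
        "hypotheses": [
            {"label": "cancer", "prior": 0.003},
            {"label": "no cancer", "prior": 0.997},
        ],
        "cues": [
            {
                "name": "hemoccult",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": "cancer",
                     "distribution": {"positive": 0.5, "negative": 0.5}},
                    {"hypothesis": "no cancer",
                     "distribution": {"positive": 0.03, "negative": 0.97}},
                ],
            }
        ],
    }
)

# two-test breast-cancer task, conditionally independent cues
TWO_TEST_JSON = json.dumps(
    {
        "hypotheses": [
            {"label": "cancer", "prior": 0.01},
            {"label": "no cancer", "prior": 0.99},
        ],
        "population": 10_000,
        "cues": [
            {
                "name": "mammogram",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": "cancer",
                     "distribution": {"positive": 0.80, "negative": 0.20}},
                    {"hypothesis": "no cancer",
                     "distribution": {"positive": 0.096, "negative": 0.904}},
                ],
            },
            {
                "name": "ultrasound",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": "cancer",
                     "distribution": {"positive": 0.95, "negative": 0.05}},
                    {"hypothesis": "no cancer",
                     "distribution": {"positive": 0.04, "negative": 0.96}},
                ],
            },
        ],
    }
)

# the same two-test task with the ultrasound written with explicit contexts
# on the mammogram value (numerically identical distributions)
TWO_TEST_CONTEXT_JSON = json.dumps(
    {
        "hypotheses": [
            {"label": "cancer", "prior": 0.01},
            {"label": "no cancer", "prior": 0.99},
        ],
        "cues": [
            {
                "name": "mammogram",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": "cancer",
                     "distribution": {"positive": 0.80, "negative": 0.20}},
                    {"hypothesis": "no cancer",
                     "distribution": {"positive": 0.096, "negative": 0.904}},
                ],
            },
            {
                "name": "ultrasound",
                "categories": ["positive", "negative"],
                "likelihoods": [
                    {"hypothesis": h, "context": {"mammogram": m},
                     "distribution": {"positive": p, "negative": round(1 - p, 10)}}
                    for h, p_by_m in [("cancer", {"positive": 0.95, "negative": 0.95}),
                                      ("no cancer", {"positive": 0.04, "negative": 0.04})]
                    for m, p in p_by_m.items()
                ],
            },
        ],
    }
)


@pytest.fixture
def mammography():
    return nf.load_task(MAMMOGRAPHY_JSON)


@pytest.fixture
def colon():
    return nf.load_task(COLON_JSON)


@pytest.fixture
def two_test():
    return nf.load_task(TWO_TEST_JSON)


@pytest.fixture
def two_test_with_contexts():
    return nf.load_task(TWO_TEST_CONTEXT_JSON)


@pytest.fixture
def chest_pain():
    return nf.green_mehr_fixture()


@pytest.fixture
def chest_pain_tree():
    return nf.green_mehr_tree()
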