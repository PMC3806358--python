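import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from attributor.corpus import Post, TextVariant, build_author_corpus  # noqa: E402
from attributor.synth import SynthConfig, generate_corpus  # noqa: E402


@pytest.fixture
def tiny_posts():
    """Three posts, two authors, one with quote markup."""
    return [
        Post(author="alice", text="Good luck everyone, fingers crossed!"),
        Post(author="bob", text="Thanks for the update. Best wishes."),
        Post(
            author="alice",
            text="[quote]Thanks for the update.[/quote]\nSame here, waiting!",
            has_inclusion=True,
        ),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """Well-separated 4-author corpus for pipeline tests (seeded)."""
    posts = generate_corpus(
        SynthConfig(seed=77, n_authors=4, posts_per_author=20, delta=0.5,
                    mean_words=40, sd_words=10)
    )
    return build_author_corpus(posts, TextVariant.ORIGINAL)
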