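from __future__ import annotations

import pytest

from needgap.corpus import Conversation, Corpus, Post, Sentence, make_sentence_id


def build_corpus(conversations, dialect: str = "MC") -> Corpus:
    """Build a corpus from nested literals.

    ``conversations`` is a list of conversations; each conversation is a list
    of posts; each post is a list of ``(text, categories, hasn)`` triples.
    """
    convs = []
    for ci, posts in enumerate(conversations):
        cid = f"c{ci}"
        plist = []
        for pi, sents in enumerate(posts):
            pid = f"p{pi}"
            slist = []
            for si, (text, cats, hasn) in enumerate(sents):
                slist.append(Sentence(
                    sentence_id=make_sentence_id(cid, pid, si),
                    conversation_id=cid, post_id=pid, index_in_post=si,
                    text=text, categories=frozenset(cats), hasn=hasn,
                ))
            plist.append(Post(post_id=pid, conversation_id=cid,
                              author=f"a{pi}", order=pi, sentences=tuple(slist)))
        convs.append(Conversation(conversation_id=cid, posts=tuple(plist)))
    return Corpus(tuple(convs), dialect=dialect)


@pytest.fixture
def toy_corpus() -> Corpus:
    return build_corpus([
        [
            [
                ("Hi to all the women out there!", {"social"}, False),
                ("I had a mastectomy and chemo last year.", {"medical"}, False),
                ("The prosthesis is hot and uncomfortable.", {"physical"}, False),
                ("Anyone else have this difficulty?", {"previous"}, True),
            ],
            [
                ("How do I choose an oncologist?", {"medical"}, True),
                ("Good luck to everyone.", {"social"}, False),
            ],
        ],
        [
            [
                ("I am 59 years old.", {"background"}, False),
                ("I was wondering about exercise after radiation.", {"wellness"}, True),
            ],
        ],
    ])
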