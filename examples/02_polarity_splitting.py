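"""Route a post's words into positive and negative emotional sub-sequences.

The emotion branch of the network never sees the whole post: a polarity
lexicon routes each word occurrence by the sign of its score, preserving
order; neutral words are dropped (the semantic branch sees them).
"""

import emoattn as ea

lexicon = ea.bundled_lexicon()
posts = ea.make_example_posts()

for post in posts:
    tokens = ea.tokenize(post.text)
    split = ea.split_by_polarity(tokens, lexicon)
    label = "depression" if post.label else "standard"
    print(f"[{label}] {post.text[:60]}...")
    print(f"  positive part: {split.pos_tokens}")
    print(f"  negative part: {split.neg_tokens}")
# The depression-indicative posts surface intense negative words
# (horrible, die, stupid, hate, shitty); the standard post has almost
# no emotional vocabulary for the emotion branch to encode.
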