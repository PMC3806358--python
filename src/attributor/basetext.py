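"""Synthetic base text for the corpus generator.

A few paragraphs of ordinary conversational English, written for this
package, used only to estimate the order-2 character transition statistics
that seed every synthetic author.  The content is deliberately mundane; the
generator cares about letter-pair statistics, not meaning.
"""

BASE_TEXT = """
The morning started slowly with a cup of tea and a long look out of the
kitchen window. The weather had turned again and the garden was covered in a
thin layer of frost that melted as soon as the sun came over the fence. I
keep meaning to plant something hardy out there but every year the season
gets away from me and the beds stay empty until spring.

We took the long road into town because the bridge was closed for repairs
again. The detour winds past the old mill and along the river where the
herons stand in the shallows waiting for fish. My daughter counts them every
time and announces the number to the whole car as if it were news of great
importance. Seven this morning, which she assures me is a record.

Someone asked me last week how the baking was going and I had to admit that
the bread has been stubborn lately. The starter sat sulking on the counter
for days and refused to rise no matter how warmly I spoke to it. In the end
I moved it to the shelf above the radiator and by Thursday it had doubled
and smelled faintly of apples, which the book says is a good sign.

The waiting is the hardest part of anything, I think. You do everything you
are supposed to do, you follow the instructions and keep your notes, and
then there is nothing left but to watch the days go past and try not to
count them too carefully. Friends tell me to keep busy and they are right,
though it is easier said than done when your mind keeps circling back to
the same question every quiet moment.

Thank you all for the kind words on the last update. It honestly helps more
than I can say to know that other people have stood in the same spot and
come out the other side with good news. I will post again on Friday when we
know more, and until then I am holding on to hope and drinking far too much
tea. Wishing everyone patience and good luck this week, whatever you are
waiting for yourselves.
"""
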