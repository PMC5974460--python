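# default cue vocabulary V for information-need pattern induction:
# wh-words, auxiliaries, pronouns, and words associated with direct or
# indirect requests for information
who
what
when
where
why
how
which
whom
do
does
did
can
could
should
would
will
shall
may
might
must
is
are
was
were
am
be
been
has
have
had
i
me
my
mine
you
your
we
us
our
they
them
their
it
this
that
these
those
there
anyone
anybody
someone
something
everyone
else
wondering
wonder
wanting
want
trouble
similar
advice
recommend
recommendation
suggestion
suggestions
question
questions
know
help
answer
answers
experience
out
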