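# English stopword list shipped with seasonwatch (pinned for reproducibility).
# Function words plus the single-letter / collapsed-contraction fragments that
# punctuation stripping leaves behind (e.g. "don't" -> "dont", "100s" -> "s").
a
about
above
after
again
against
all
am
an
and
any
are
arent
as
at
be
because
been
before
being
below
between
both
but
by
cant
cannot
could
couldnt
d
did
didnt
do
does
doesnt
doing
dont
down
during
each
few
for
from
further
had
hadnt
has
hasnt
have
havent
having
he
hed
her
here
hers
herself
hes
him
himself
his
how
i
id
if
ill
im
in
into
is
isnt
it
its
itself
ive
ll
m
me
more
most
my
myself
no
nor
not
o
of
off
on
once
only
or
other
ought
our
ours
ourselves
out
over
own
re
s
same
she
shes
should
shouldnt
so
some
such
t
than
that
thats
the
their
theirs
them
themselves
then
there
theres
these
they
theyre
this
those
through
to
too
under
until
up
ve
very
was
wasnt
we
were
werent
weve
what
whats
when
where
which
while
who
whom
why
will
with
wont
would
wouldnt
y
you
youll
your
youre
yours
yourself
yourselves
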