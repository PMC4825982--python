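;;; Small RP-style example pronunciation lexicon (IPA, one entry per line:
;;; WORD<TAB>PH1 PH2 ...). Covers the 44-symbol default inventory. A demo
;;; fixture, not a linguistic resource.
the	ð ə
a	ə
and	æ n d
of	ɒ v
to	t uː
in	ɪ n
it	ɪ t
is	ɪ z
was	w ɒ z
i	aɪ
for	f ɔː
you	j uː
he	h iː
be	b iː
with	w ɪ ð
on	ɒ n
that	ð æ t
by	b aɪ
at	æ t
are	ɑː
not	n ɒ t
this	ð ɪ s
but	b ʌ t
had	h æ d
his	h ɪ z
they	ð eɪ
from	f r ɒ m
she	ʃ iː
which	w ɪ tʃ
or	ɔː
we	w iː
an	æ n
were	w ɜː
her	h ɜː
all	ɔː l
there	ð eə
one	w ʌ n
would	w ʊ d
will	w ɪ l
what	w ɒ t
so	s əʊ
up	ʌ p
out	aʊ t
if	ɪ f
about	ə b aʊ t
who	h uː
get	g e t
go	g əʊ
me	m iː
when	w e n
make	m eɪ k
can	k æ n
like	l aɪ k
time	t aɪ m
no	n əʊ
just	dʒ ʌ s t
him	h ɪ m
know	n əʊ
take	t eɪ k
people	p iː p ə l
year	j ɪə
your	j ɔː
good	g ʊ d
some	s ʌ m
could	k ʊ d
them	ð e m
see	s iː
other	ʌ ð ə
than	ð æ n
then	ð e n
now	n aʊ
look	l ʊ k
only	əʊ n l ɪ
come	k ʌ m
its	ɪ t s
over	əʊ v ə
think	θ ɪ ŋ k
also	ɔː l s əʊ
back	b æ k
after	ɑː f t ə
use	j uː z
two	t uː
how	h aʊ
our	aʊ ə
work	w ɜː k
first	f ɜː s t
well	w e l
way	w eɪ
even	iː v ə n
new	n j uː
want	w ɒ n t
because	b ɪ k ɒ z
any	e n ɪ
these	ð iː z
give	g ɪ v
day	d eɪ
most	m əʊ s t
us	ʌ s
row	r əʊ
low	l əʊ
boy	b ɔɪ
poor	p ʊə
measure	m e ʒ ə
church	tʃ ɜː tʃ
judge	dʒ ʌ dʒ
thin	θ ɪ n
sing	s ɪ ŋ
ship	ʃ ɪ p
vision	v ɪ ʒ ə n
here	h ɪə
hair	h eə
cure	k j ʊə
it's	ɪ t s
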