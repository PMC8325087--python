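# bundled word-polarity lexicon: word<TAB>score in [-1,1]
advice	0.5
baby	0.5
basically	0.5
believe	0.5
best	0.7
better	0.55
big	0.5
birthday	0.5
boyfriend	0.5
brother	0.5
care	0.5
change	0.5
child	0.5
close	0.5
conversation	0.5
deal	0.5
enjoy	0.7
eventually	0.5
family	0.5
father	0.5
friend	0.5
friends	0.5
friendship	0.5
fun	0.7
good	0.6
great	0.7
happiness	0.8
happy	0.8
hard	0.5
help	0.5
high	0.5
honestly	0.5
hope	0.6
job	0.5
kids	0.5
love	0.8
loved	0.8
mad	0.5
married	0.5
mental	0.5
mind	0.5
money	0.5
motivation	0.5
moved	0.5
new	0.5
nice	0.6
normal	0.5
okay	0.5
real	0.5
reason	0.5
remember	0.5
saying	0.5
self	0.5
sister	0.5
sleep	0.5
social	0.5
spend	0.5
sure	0.5
therapist	0.5
together	0.5
understand	0.5
wanted	0.5
work	0.5
working	0.5
afraid	-0.5
alone	-0.5
angry	-0.5
annoyed	-0.5
anxiety	-0.5
awkward	-0.5
bad	-0.5
bitch	-0.5
broke	-0.5
broken	-0.5
cancer	-0.5
confused	-0.5
constantly	-0.5
cry	-0.5
crying	-0.5
cut	-0.5
dark	-0.5
dead	-0.85
depressed	-0.75
depression	-0.7
die	-0.9
died	-0.5
difficult	-0.5
fault	-0.5
fuck	-0.65
fucking	-0.65
hang	-0.5
hate	-0.7
hell	-0.5
horrible	-0.8
hospital	-0.5
hurt	-0.5
ignore	-0.5
illness	-0.5
issues	-0.5
kill	-0.9
lonely	-0.5
lose	-0.5
lost	-0.5
miserable	-0.8
nothing	-0.5
old	-0.5
pain	-0.5
pregnant	-0.5
problem	-0.5
problems	-0.5
reddit	-0.5
relationship	-0.5
reply	-0.5
sad	-0.5
scared	-0.5
selfish	-0.5
shit	-0.5
shitty	-0.7
sick	-0.4
sorry	-0.5
stop	-0.5
stupid	-0.6
suicidal	-0.95
suicide	-0.95
therapy	-0.5
tired	-0.5
toxic	-0.5
upset	-0.5
wait	-0.5
weird	-0.5
worse	-0.5
worst	-0.75
wrong	-0.5
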