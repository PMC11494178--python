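the 330
be 200
to 190
of 180
and 170
a 160
in 150
that 120
have 110
it 100
for 95
not 90
on 88
with 85
he 80
as 78
you 75
do 72
at 70
this 68
but 66
his 64
by 62
from 60
they 58
we 56
say 54
her 52
she 50
or 48
an 46
will 44
my 42
one 40
all 38
would 36
there 34
their 32
what 30
so 28
up 26
out 24
if 22
about 20
who 18
get 17
which 16
go 15
me 14
when 13
make 12
can 12
like 11
time 11
no 10
just 10
him 9
know 9
take 9
people 8
into 8
year 8
your 8
good 8
some 7
could 7
them 7
see 7
other 7
than 6
then 6
now 6
look 6
only 6
come 6
its 5
over 5
think 5
also 5
back 5
after 5
use 5
two 5
how 5
our 5
work 5
first 5
well 4
way 4
even 4
new 4
want 4
because 4
any 4
these 4
give 4
day 4
most 4
us 4
is 120
was 90
are 70
been 30
has 25
had 40
were 30
said 20
did 10
water 6
birch 3
canoe 3
slid 3
smooth 3
planks 3
glue 2
sheet 2
dark 2
blue 2
background 2
depth 2
well 2
chicken 2
leg 2
rare 2
dish 2
rice 2
often 3
served 2
round 2
bowls 2
juice 2
lemons 2
makes 2
fine 2
punch 2
box 2
thrown 2
beside 2
parked 2
truck 2
hogs 2
fed 2
chopped 2
corn 2
garbage 2
hours 2
steady 2
facts 2
strength 2
salt 2
breeze 2
came 2
across 2
sea 2
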