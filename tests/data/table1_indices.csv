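name,lambda1,lambda2
Alv1.1,395,404
Alv1.2,575,604
Alv1.3,711,732
Alv2.1,404,489
Alv2.2,595,662
Alv3.1,446,473
Alv3.2,531,555
Alv3.3,586,622
Alv4.1,446,489
Alv4.2,569,600
Alv4.3,611,671
Alv5.1,484,522
Alv5.2,695,720
Alv6.1,400,418
Alv6.2,460,484
Alv6.3,724,768
PLv1.1,437,473
PLv1.2,680,737
PLv2.1,411,473
PLv2.2,640,671
PLv3.1,429,473
PLv3.2,576,640
PLv4.1,406,418
PLv4.2,533,582
GLv3.1,409,477
GLv3.2,640,722
TLv5.1,415,442
TLv5.2,471,486
TLv5.3,500,544
TLv5.4,675,717
SLv5.1,429,444
SLv5.2,506,544
SLv5.3,577,604
SLv5.4,662,708
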