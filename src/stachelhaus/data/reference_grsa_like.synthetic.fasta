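>grsa_like_synthetic canonical-Phe-code planted at GrsA signature positions; randomly generated background (seed 1746); synthetic stand-in, not the real GrsA domain
WADMDTFNSCVCIPPCISGNMQPWNKTRMSIPDEYKFKSRHFYNLLYPSFNDMYTCYRTS
VWYFDCRDFSVHQWANYSRLKYQAAWSRTKQGTNFDSSCIDELRCGKYIKTVETNDYDVI
NYPDQFVQGWDLIKQYDSKYSIRHKVQYCYWKCERLCAFSDAQCHDIKQRWTENEVTPLS
LSVKRLDQDYYCSGCPEDACGYATFLVNCQHLSEPEPCDCSNPYHRLPDTDIGNDAPIWF
SMYGFQWRKSPASLCSWDHTIVRGKCWQFEVPNKILLTKPDITFNMLHIICNIENDGYIG
ARVGFLFGSIRCIRFNIMQENAQFIPRQMICNMGCVVYFSCFKTTCVRVKVNQIMPYADM
YCMTVGAERPHKPEKVTPEHWAGAESYVGHTHWDIMHTIVNFEKWAVFNNMMVIMECTTA
KAWYRLKLWAYDAFFHMCHKWFKIWYEKKGWRFVIHRNPMNLGYKVNSCMYHVDHMKWYI
LGSWQWRVAHSGWGAQFYPSTRYYYNLSMPAMLQGVKACDSSIAKSYCPL
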