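synonym	canonical
obinutuzumab	obinutuzumab
gazyva	obinutuzumab
gazyvaro	obinutuzumab
ga101	obinutuzumab
ga 101	obinutuzumab
ro5072759	obinutuzumab
rituximab	rituximab
rituxan	rituximab
mabthera	rituximab
ibrutinib	ibrutinib
imbruvica	ibrutinib
venetoclax	venetoclax
venclexta	venetoclax
bendamustine	bendamustine
treanda	bendamustine
bendeka	bendamustine
cyclophosphamide	cyclophosphamide
cytoxan	cyclophosphamide
lenalidomide	lenalidomide
revlimid	lenalidomide
acalabrutinib	acalabrutinib
calquence	acalabrutinib
chlorambucil	chlorambucil
leukeran	chlorambucil
prednisone	prednisone
methotrexate	methotrexate
cisplatin	cisplatin
paclitaxel	paclitaxel
pembrolizumab	pembrolizumab
keytruda	pembrolizumab
nivolumab	nivolumab
opdivo	nivolumab
trastuzumab	trastuzumab
herceptin	trastuzumab
infliximab	infliximab
remicade	infliximab
adalimumab	adalimumab
humira	adalimumab
tocilizumab	tocilizumab
actemra	tocilizumab
mycophenolate mofetil	mycophenolate mofetil
cellcept	mycophenolate mofetil
azathioprine	azathioprine
imuran	azathioprine
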